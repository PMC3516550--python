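"""End-to-end orchestration: simulate -> scan -> eqtl -> causality -> network
-> rank -> enrich, with a manifest of produced artifacts.

``analyze_panel`` is the in-memory core used both by the CLI and by the
recovery experiments: it maps the clinical trait, selects the top two trait
loci, scans all genes, intersects eQTL peaks with the trait intervals,
filters the locus gene lists by the causal/reactive test, builds the
cross-group PPI network and ranks genes by TIE with a permutation null.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .causality import CausalCall, classify_triplet, filter_causal_reactive
from .enrich import TermAnnotation, hypergeom_enrich
from .eqtl import annotate_cis, locus_gene_sets, overlap_with_trait_qtl, scan_all_genes
from .model import ValidationError
from .network import (
    build_cross_network,
    cross_frequency,
    format_frequency,
    write_node_attributes,
    write_sif,
)
from .qtl import genomewide_threshold, scan_trait, select_top_loci
from .scoring import score_network
from .simulate import CrossConfig, simulate_panel

logger = logging.getLogger("tiescore")

ALL_STAGES = ("simulate", "scan", "eqtl", "causality", "network", "rank", "enrich")


@dataclass
class PipelineConfig:
    """Parameters of a full (synthetic-input) pipeline run."""

    outdir: str = "tiescore_out"
    seed: int = 0
    alpha: float = 0.05
    n_perm_threshold: int = 200
    n_perm_tie: int = 200
    cis_window_bp: int = 10_000_000
    min_degree: int = 5
    lod_drop: float = 1.5
    ip_form: str = "product"
    trait_name: str = "insulin"
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    cross: dict = field(default_factory=dict)  # CrossConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0, 1]")
        for key in self.stages:
            if key not in ALL_STAGES:
                raise ValidationError(f"unknown stage {key!r}")
        # instantiating checks the cross-config invariants too
        self.cross_config()

    def cross_config(self) -> CrossConfig:
        return CrossConfig(seed=self.seed, **self.cross)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PanelResult:
    """In-memory results of one analysis run."""

    curve: object
    threshold: float
    intervals: list
    eqtl_calls: list
    causal_calls: list
    group1: set
    group2: set
    network: object
    rank: pd.DataFrame


def classify_locus_groups(
    genotypes, expression, trait, groups: tuple, intervals
) -> list[CausalCall]:
    """Causality test for every gene in each locus group at its peak marker."""
    common = [m for m in genotypes.mice if m in set(expression.mice)]
    gidx = [genotypes.mice.index(m) for m in common]
    eidx = {m: j for j, m in enumerate(expression.mice)}
    ecol = [eidx[m] for m in common]
    t = trait.reindex(common)
    calls = []
    for label, interval, group in zip(("locus1", "locus2"), intervals, groups):
        codes = genotypes.marker_codes(interval.peak_marker_id)[gidx]
        for gene in sorted(group):
            row = expression.gene_values(gene)[ecol]
            try:
                call = classify_triplet(codes, row, t, gene_id=gene, locus=label)
            except ValidationError:
                call = CausalCall(
                    gene_id=gene, locus=label, scores={}, label="independent", margin=0.0
                )
            calls.append(call)
    return calls


def analyze_panel(
    genotypes,
    gmap,
    expression,
    annotation,
    trait,
    ppi,
    *,
    alpha: float = 0.05,
    n_perm_threshold: int = 200,
    n_perm_tie: int = 200,
    cis_window_bp: int = 10_000_000,
    min_degree: int = 5,
    lod_drop: float = 1.5,
    ip_form: str = "product",
    lod_min: Optional[float] = None,
    use_causality: bool = True,
    seed: int = 0,
) -> PanelResult:
    """Run the full integrative analysis on one panel.

    The two trait loci are the top two chromosome peaks of the clinical-trait
    scan (the study design: focus on the strongest pair of loci), with
    1.5-LOD support intervals; ``lod_min`` for eQTL peaks defaults to the
    trait's genome-wide permutation threshold.
    """
    threshold = genomewide_threshold(
        genotypes, gmap, trait, n_perm=n_perm_threshold, alpha=alpha, seed=seed
    )
    curve = scan_trait(genotypes, gmap, trait)
    intervals = select_top_loci(curve, k=2, drop=lod_drop, threshold=threshold)
    if lod_min is None:
        lod_min = threshold
    calls = scan_all_genes(genotypes, gmap, expression, lod_min=lod_min)
    calls = annotate_cis(calls, annotation, gmap, cis_window_bp)
    calls = overlap_with_trait_qtl(calls, intervals)
    g1, g2 = locus_gene_sets(calls)
    causal_calls: list[CausalCall] = []
    if use_causality:
        causal_calls = classify_locus_groups(
            genotypes, expression, trait, (g1, g2), intervals
        )
        kept = filter_causal_reactive(causal_calls)
        g1 &= kept.get("locus1", set())
        g2 &= kept.get("locus2", set())
    network = build_cross_network(ppi, g1, g2)
    rank = score_network(
        network,
        expression,
        trait,
        n_perm=n_perm_tie,
        seed=seed + 1,
        min_degree=min_degree,
        form=ip_form,
    )
    return PanelResult(
        curve=curve,
        threshold=threshold,
        intervals=intervals,
        eqtl_calls=calls,
        causal_calls=causal_calls,
        group1=g1,
        group2=g2,
        network=network,
        rank=rank,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Each stage writes its outputs under ``config.outdir`` and contributes a
    manifest entry (outputs with checksums, parameters, seed).  The run is a
    pure function of (config, seed): a rerun produces identical artifacts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = {s: config.stages.get(s, True) for s in ALL_STAGES}
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, outputs: list[Path], params: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "params": params,
        }

    cross = config.cross_config()
    current = None
    try:
        # ---- simulate -------------------------------------------------------
        genotypes, gmap, expr, annot, trait, truth, ppi = simulate_panel(cross)
        if enabled["simulate"]:
            current = "simulate"
            tio.write_genotypes(genotypes, out / "genotypes.tsv")
            tio.write_map(gmap, out / "map.tsv")
            tio.write_expression(expr, out / "expression.tsv")
            tio.write_annotation(annot, out / "genes.tsv")
            tio.write_trait(trait, out / "trait.tsv")
            tio.write_edges(ppi, out / "ppi.tsv")
            truth_tab = pd.DataFrame(
                {
                    "gene": sorted(truth.regulator),
                    "regulator": [truth.regulator[g] for g in sorted(truth.regulator)],
                    "role": [truth.role[g] for g in sorted(truth.regulator)],
                }
            )
            truth_tab.to_csv(out / "truth.tsv", sep="\t", index=False)
            record(
                "simulate",
                [out / f for f in (
                    "genotypes.tsv", "map.tsv", "expression.tsv", "genes.tsv",
                    "trait.tsv", "ppi.tsv", "truth.tsv",
                )],
                {"seed": cross.seed, "n_mice": cross.n_mice},
            )

        current = "analysis"
        result = analyze_panel(
            genotypes, gmap, expr, annot, trait, ppi,
            alpha=config.alpha,
            n_perm_threshold=config.n_perm_threshold,
            n_perm_tie=config.n_perm_tie,
            cis_window_bp=config.cis_window_bp,
            min_degree=config.min_degree,
            lod_drop=config.lod_drop,
            ip_form=config.ip_form,
            use_causality=enabled["causality"],
            seed=config.seed,
        )
        if not enabled["causality"]:
            manifest["notes"] = ["causality stage skipped: unfiltered overlap sets used"]

        # ---- scan -----------------------------------------------------------
        if enabled["scan"]:
            current = "scan"
            result.curve.table.to_csv(out / "lod_curve.tsv", sep="\t", index=False)
            iv = pd.DataFrame([dataclasses.asdict(i) for i in result.intervals])
            iv.to_csv(out / "intervals.tsv", sep="\t", index=False)
            record(
                "scan",
                [out / "lod_curve.tsv", out / "intervals.tsv"],
                {"alpha": config.alpha, "threshold": result.threshold},
            )

        # ---- eqtl -----------------------------------------------------------
        if enabled["eqtl"]:
            current = "eqtl"
            eq = pd.DataFrame([dataclasses.asdict(c) for c in result.eqtl_calls])
            eq.to_csv(out / "eqtl_calls.tsv", sep="\t", index=False)
            record("eqtl", [out / "eqtl_calls.tsv"], {"lod_min": result.threshold})

        # ---- causality ------------------------------------------------------
        if enabled["causality"]:
            current = "causality"
            ca = pd.DataFrame(
                [
                    {
                        "gene": c.gene_id,
                        "locus": c.locus,
                        "label": c.label,
                        "margin": c.margin,
                    }
                    for c in result.causal_calls
                ]
            )
            ca.to_csv(out / "causal_calls.tsv", sep="\t", index=False)
            record("causality", [out / "causal_calls.tsv"], {})

        # ---- network --------------------------------------------------------
        if enabled["network"]:
            current = "network"
            write_sif(result.network, out / "cross_network.sif")
            write_node_attributes(result.network, out / "cross_network_nodes.tsv")
            freq = cross_frequency(result.network)
            (out / "network_summary.txt").write_text(
                f"group1\t{freq.n_group1}\ngroup2\t{freq.n_group2}\n"
                f"edges\t{freq.n_edges}\nfrequency\t{format_frequency(freq)}\n"
            )
            record(
                "network",
                [out / "cross_network.sif", out / "cross_network_nodes.tsv",
                 out / "network_summary.txt"],
                {"frequency_percent": freq.percent},
            )

        # ---- rank -----------------------------------------------------------
        if enabled["rank"]:
            current = "rank"
            result.rank.to_csv(out / "rank_table.tsv", sep="\t", index=False)
            record(
                "rank",
                [out / "rank_table.tsv"],
                {"n_perm": config.n_perm_tie, "min_degree": config.min_degree},
            )

        # ---- enrich ---------------------------------------------------------
        if enabled["enrich"]:
            current = "enrich"
            terms = [
                TermAnnotation(
                    term_id=f"class:{reg}",
                    term_name=f"planted regulator class {reg}",
                    genes=frozenset(
                        g for g, r in truth.regulator.items() if r == reg
                    ),
                )
                for reg in sorted(set(truth.regulator.values()))
                if any(r == reg for r in truth.regulator.values())
            ]
            query = result.group1 | result.group2
            if query:
                table = hypergeom_enrich(query, terms, set(truth.regulator))
                table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                record("enrich", [out / "enrichment.tsv"], {"query_size": len(query)})
    except Exception:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline aborted in stage %s; partial outputs retained", current)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
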