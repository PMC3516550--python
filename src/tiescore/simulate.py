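"""Synthetic F2 intercross with a two-locus trait architecture.

The generator emulates the study design the pipeline targets: an obese F2
panel (two inbred founder strains), a clinical trait (plasma insulin) linked
to two loci, cis- and trans-regulated expression traits, a planted hub gene
that is driven by both loci and negatively regulates the trait, reactive
genes that respond to the trait, and a planted PPI graph in which the hub
mediates the cross-group interactions.  A :class:`SynthTruth` record carries
the ground truth for recovery tests.

Model (all effects standardized; ``x_l`` is the genotype code at the marker
nearest locus ``l``, centered and scaled to unit variance):

* hub expression  ``E_hub = a1*x1 + a2*x2 + sigma_h * e``
* trait           ``T = beta1*x1 + beta2*x2 + gamma_hub*E_hub + sigma_T * eps``

``a1, a2`` are derived from the requested per-locus trait R^2 so that the
TOTAL locus effect (direct ``beta`` plus the hub-mediated path) hits the
target; with the default ``beta1 = beta2 = 0`` the trait's linkage to both
loci is entirely hub-mediated, so conditioning the trait scan on hub
expression abolishes both QTLs.  Defaults target locus R^2 of 10% and 8%
and a hub-trait correlation of -0.6.

Meiosis uses the Haldane (no-interference) map function; each F2 mouse is
the sum of two independently simulated gametes per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    PpiNetwork,
    TraitVector,
    ValidationError,
)

HUB_GENE_ID = "g_hub"


@dataclass(frozen=True)
class CrossConfig:
    """Study conditions for the synthetic cross.

    The defaults are the package's scaled-down analogue of the study: 250
    mice, a 5-chromosome genome with 30 markers per chromosome, two trait
    loci on chromosomes 1 and 2 with target R^2 of 10% and 8%, and a hub
    whose expression-trait correlation is about -0.6.
    """

    n_mice: int = 250
    chromosomes: tuple = (
        ("1", 90.0, 30),
        ("2", 90.0, 30),
        ("3", 90.0, 30),
        ("4", 90.0, 30),
        ("5", 90.0, 30),
    )
    locus1: tuple = ("1", 45.0)
    locus2: tuple = ("2", 45.0)
    # gene-roster sizes
    n_cis_genes: int = 30
    n_trans1_genes: int = 40
    n_trans2_genes: int = 25
    n_both_genes: int = 10
    n_reactive1_genes: int = 25
    n_reactive2_genes: int = 25
    n_null_genes: int = 60
    hub_neighbors_per_group: int = 10
    # effect sizes (standardized scales)
    beta1: float = 0.0
    beta2: float = 0.0
    gamma_hub: float = -0.6
    locus_r2: tuple = (0.10, 0.08)
    eqtl_effect: float = 1.0
    expr_noise_sd: float = 1.0
    # trait -> reactive-gene coupling; negative by default so the hub's
    # partner group shares the hub's (negative) trait correlation, as the
    # top-ranked genes do in the tissue this emulates
    reactive_effect: float = -1.0
    # network
    background_edges: int = 300
    # bookkeeping
    bp_per_cM: int = 500_000
    hub_mode: str = "causal"  # "causal" (hub drives trait) or "reactive"
    tissue: str = "islet"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.locus1[0] == self.locus2[0]:
            raise ValidationError("locus1 and locus2 must be on distinct chromosomes")
        chrom_names = [c[0] for c in self.chromosomes]
        for locus in (self.locus1, self.locus2):
            if locus[0] not in chrom_names:
                raise ValidationError(f"locus chromosome {locus[0]!r} not in genome")
        for name, length, n in self.chromosomes:
            if length <= 0 or n < 1:
                raise ValidationError(f"chromosome {name!r}: invalid length/markers")
        counts = (
            self.n_cis_genes,
            self.n_trans1_genes,
            self.n_trans2_genes,
            self.n_both_genes,
            self.n_reactive1_genes,
            self.n_reactive2_genes,
            self.n_null_genes,
            self.hub_neighbors_per_group,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("gene counts must be >= 0")
        if self.hub_mode not in ("causal", "reactive"):
            raise ValidationError("hub_mode must be 'causal' or 'reactive'")
        if min(self.n_reactive1_genes, self.n_reactive2_genes) < self.hub_neighbors_per_group:
            raise ValidationError(
                "need at least hub_neighbors_per_group reactive genes per group"
            )


@dataclass
class SynthTruth:
    """Ground truth of a synthetic panel, for recovery tests."""

    hub_gene_id: str
    regulator: dict  # gene -> locus1 | locus2 | both | cis | none
    role: dict  # gene -> causal | reactive | independent
    hub_neighbors_group1: list = field(default_factory=list)
    hub_neighbors_group2: list = field(default_factory=list)
    planted_edges: list = field(default_factory=list)
    variance_fractions: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)

    def group_genes(self, which: str) -> set:
        """Truth gene set linked to locus1 or locus2 ('both' counts in each)."""
        want = {which, "both"}
        return {g for g, r in self.regulator.items() if r in want}


def haldane_r(distance_cM: float) -> float:
    """Haldane map function: recombination fraction for a cM distance.

    r = (1 - exp(-2 d)) / 2 with d in Morgans; no crossover interference.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValidationError("map distance must be nonnegative")
    out = (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0
    return float(out) if np.isscalar(distance_cM) else out


def build_map(config: CrossConfig) -> GeneticMap:
    """Evenly spaced markers along each chromosome of the config genome."""
    rows = []
    for name, length, n in config.chromosomes:
        cms = np.linspace(0.0, length, n)
        for k, cm in enumerate(cms):
            rows.append(
                {
                    "marker": f"c{name}m{k:03d}",
                    "chromosome": name,
                    "cM": float(cm),
                    "bp": int(round(cm * config.bp_per_cM)) + 1,
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def simulate_gametes(
    rng: np.random.Generator, positions_cM: np.ndarray, n_gametes: int
) -> np.ndarray:
    """Simulate F1 gametes along one chromosome (Markov chain, Haldane).

    Returns an (n_gametes, n_markers) 0/1 allele matrix; adjacent markers
    recombine independently with probability ``haldane_r`` of their distance
    (no crossover interference).
    """
    positions_cM = np.asarray(positions_cM, dtype=float)
    alleles = np.empty((n_gametes, positions_cM.size), dtype=np.int8)
    alleles[:, 0] = rng.random(n_gametes) < 0.5
    for k in range(1, positions_cM.size):
        r = haldane_r(positions_cM[k] - positions_cM[k - 1])
        swap = rng.random(n_gametes) < r
        alleles[:, k] = alleles[:, k - 1] ^ swap
    return alleles


def simulate_cross(config: CrossConfig) -> tuple[GenotypeMatrix, GeneticMap]:
    """Simulate F2 genotypes: two independent gametes per chromosome.

    Each gamete follows a Markov chain along the markers with Haldane
    transition (recombination) probabilities; the F2 genotype at a marker is
    the sum of the two gamete alleles, so marginal frequencies are 1:2:1.
    Deterministic given ``config`` (seeded from ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    gmap = build_map(config)
    n = config.n_mice
    blocks = []
    for name, length, n_mark in config.chromosomes:
        cms = gmap.table.loc[gmap.table["chromosome"] == name, "cM"].to_numpy()
        alleles = simulate_gametes(rng, cms, 2 * n)
        blocks.append(alleles[:n] + alleles[n:])
    codes = np.concatenate(blocks, axis=1).astype(float)
    mice = [f"M{i:04d}" for i in range(n)]
    return GenotypeMatrix(mice=mice, gmap=gmap, codes=codes), gmap


def _standardized_locus(codes: np.ndarray) -> np.ndarray:
    # F2 additive variance of the 0/1/2 code is 1/2 under 1:2:1
    return (codes - 1.0) / np.sqrt(0.5)


def _structural_coefficients(config: CrossConfig) -> dict:
    """Derive hub/trait coefficients from the requested variance targets."""
    r2_1, r2_2 = config.locus_r2
    gamma = config.gamma_hub
    if config.hub_mode == "causal":
        if gamma == 0:
            raise ValidationError("causal hub mode needs gamma_hub != 0")
        # total (direct + mediated) locus effect on the trait; negative sign:
        # the high-risk-strain allele raises hub expression which lowers the trait
        b_tot = (-np.sqrt(r2_1), -np.sqrt(r2_2))
        a1 = (b_tot[0] - config.beta1) / gamma
        a2 = (b_tot[1] - config.beta2) / gamma
        if a1 < 0 or a2 < 0:
            raise ValidationError(
                "direct effects beta exceed the locus R^2 target; no hub path left"
            )
        sigma_h2 = 1.0 - a1**2 - a2**2
        if sigma_h2 <= 0:
            raise ValidationError("hub eQTL effects exceed unit variance")
        struct_var = b_tot[0] ** 2 + b_tot[1] ** 2 + gamma**2 * sigma_h2
        sigma_t2 = 1.0 - struct_var
        if sigma_t2 <= 0:
            raise ValidationError("structural trait variance exceeds 1")
        return {
            "a1": a1,
            "a2": a2,
            "sigma_h": float(np.sqrt(sigma_h2)),
            "sigma_t": float(np.sqrt(sigma_t2)),
            "b_tot": b_tot,
        }
    # reactive hub: trait linked directly, hub responds to the trait
    b1 = config.beta1 if config.beta1 != 0 else -np.sqrt(r2_1)
    b2 = config.beta2 if config.beta2 != 0 else -np.sqrt(r2_2)
    sigma_t2 = 1.0 - b1**2 - b2**2
    if sigma_t2 <= 0:
        raise ValidationError("direct locus effects exceed unit variance")
    sigma_h2 = 1.0 - gamma**2
    if sigma_h2 <= 0:
        raise ValidationError("|gamma_hub| must be < 1 in reactive mode")
    return {
        "b1": b1,
        "b2": b2,
        "sigma_t": float(np.sqrt(sigma_t2)),
        "sigma_h": float(np.sqrt(sigma_h2)),
        "b_tot": (b1, b2),
    }


def simulate_expression_and_trait(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: CrossConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, TraitVector, SynthTruth]:
    """Plant the expression architecture and the clinical trait.

    Gene classes (sizes from the config):

    * cis genes: driven by the genotype at their own (randomly chosen)
      marker, annotated at that marker's bp;
    * trans1 / trans2 / both genes: driven by the genotype at locus 1 and/or
      locus 2 but independent of the trait given the loci ("independent"
      causal role — they should be filtered out downstream);
    * hub: driven by both loci; its expression feeds the trait with
      coefficient ``gamma_hub`` (causal role "causal");
    * reactive genes: driven by the trait itself (role "reactive"; linked to
      both loci through the trait); the hub's planted PPI neighbors are drawn
      from these, split into two nominal locus groups;
    * null genes: pure noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(genotypes.mice)
    coef = _structural_coefficients(config)

    m1 = gmap.nearest_marker(*config.locus1)
    m2 = gmap.nearest_marker(*config.locus2)
    x1 = _standardized_locus(genotypes.marker_codes(m1))
    x2 = _standardized_locus(genotypes.marker_codes(m2))
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValidationError("missing genotypes at trait loci not supported")

    roster: list[tuple[str, str, str]] = []  # (gene, regulator, role)

    def add(prefix: str, count: int, regulator: str, role: str) -> list[str]:
        ids = [f"{prefix}{i:03d}" for i in range(count)]
        roster.extend((g, regulator, role) for g in ids)
        return ids

    cis_ids = add("cis", config.n_cis_genes, "cis", "independent")
    trans1_ids = add("t1_", config.n_trans1_genes, "locus1", "independent")
    trans2_ids = add("t2_", config.n_trans2_genes, "locus2", "independent")
    both_ids = add("tb_", config.n_both_genes, "both", "independent")
    react1_ids = add("r1_", config.n_reactive1_genes, "both", "reactive")
    react2_ids = add("r2_", config.n_reactive2_genes, "both", "reactive")
    null_ids = add("nul", config.n_null_genes, "none", "independent")
    hub_role = "causal" if config.hub_mode == "causal" else "reactive"
    roster.append((HUB_GENE_ID, "both", hub_role))

    genes = [g for g, _, _ in roster]
    n_genes = len(genes)
    if config.n_cis_genes > gmap.n_markers:
        raise ValidationError("more cis genes requested than placeable markers")

    # --- structural variables -------------------------------------------------
    eps = rng.standard_normal
    if config.hub_mode == "causal":
        e_hub = coef["a1"] * x1 + coef["a2"] * x2 + coef["sigma_h"] * eps(n)
        trait_vals = (
            config.beta1 * x1
            + config.beta2 * x2
            + config.gamma_hub * e_hub
            + coef["sigma_t"] * eps(n)
        )
    else:
        trait_vals = coef["b1"] * x1 + coef["b2"] * x2 + coef["sigma_t"] * eps(n)
        e_hub = config.gamma_hub * trait_vals + coef["sigma_h"] * eps(n)

    # --- expression matrix ----------------------------------------------------
    values = np.empty((n_genes, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    noise = config.expr_noise_sd

    # cis genes at random distinct markers
    cis_marker_idx = rng.choice(gmap.n_markers, size=len(cis_ids), replace=False)
    marker_table = gmap.table
    for g, j in zip(cis_ids, cis_marker_idx):
        xg = _standardized_locus(genotypes.codes[:, j])
        values[gene_index[g]] = config.eqtl_effect * xg + noise * eps(n)
    for g in trans1_ids:
        values[gene_index[g]] = config.eqtl_effect * x1 + noise * eps(n)
    for g in trans2_ids:
        values[gene_index[g]] = config.eqtl_effect * x2 + noise * eps(n)
    for g in both_ids:
        xg = (x1 + x2) / np.sqrt(2.0)
        values[gene_index[g]] = config.eqtl_effect * xg + noise * eps(n)
    for g in react1_ids + react2_ids:
        values[gene_index[g]] = config.reactive_effect * trait_vals + noise * eps(n)
    for g in null_ids:
        values[gene_index[g]] = eps(n)
    values[gene_index[HUB_GENE_ID]] = e_hub

    # --- annotation -----------------------------------------------------------
    # non-cis genes are placed on chromosomes carrying neither trait locus so
    # that their linkage is unambiguously trans
    away = marker_table[
        ~marker_table["chromosome"].isin([config.locus1[0], config.locus2[0]])
    ]
    if away.empty:
        away = marker_table
    rows = []
    for g, j in zip(cis_ids, cis_marker_idx):
        row = marker_table.iloc[j]
        rows.append({"gene": g, "chromosome": row["chromosome"], "bp": row["bp"]})
    rest = [g for g in genes if g not in set(cis_ids)]
    spots = away.iloc[rng.integers(0, len(away), size=len(rest))]
    for g, (_, row) in zip(rest, spots.iterrows()):
        rows.append({"gene": g, "chromosome": row["chromosome"], "bp": row["bp"]})
    annotation = GeneAnnotation(pd.DataFrame(rows))

    expr = ExpressionMatrix(
        genes=genes, mice=list(genotypes.mice), values=values, tissue=config.tissue
    )
    trait = TraitVector(
        mice=list(genotypes.mice), values=trait_vals, name="insulin"
    )

    # --- truth record ---------------------------------------------------------
    b1t, b2t = coef["b_tot"]
    frac = {
        "locus1": float(b1t**2),
        "locus2": float(b2t**2),
        "hub_path_noise": float(
            (config.gamma_hub**2) * coef["sigma_h"] ** 2
            if config.hub_mode == "causal"
            else 0.0
        ),
        "residual": float(coef["sigma_t"] ** 2),
    }
    hub_corr = float(np.corrcoef(e_hub, trait_vals)[0, 1])
    realized = {
        "r2_locus1": float(np.corrcoef(x1, trait_vals)[0, 1] ** 2),
        "r2_locus2": float(np.corrcoef(x2, trait_vals)[0, 1] ** 2),
        "hub_trait_corr": hub_corr,
    }
    truth = SynthTruth(
        hub_gene_id=HUB_GENE_ID,
        regulator={g: reg for g, reg, _ in roster},
        role={g: role for g, _, role in roster},
        hub_neighbors_group1=react1_ids[: config.hub_neighbors_per_group],
        hub_neighbors_group2=react2_ids[: config.hub_neighbors_per_group],
        variance_fractions=frac,
        realized=realized,
    )
    truth.planted_edges = [
        (HUB_GENE_ID, g)
        for g in truth.hub_neighbors_group1 + truth.hub_neighbors_group2
    ]
    return expr, annotation, trait, truth


def plant_network(truth: SynthTruth, config: CrossConfig) -> PpiNetwork:
    """Planted PPI: hub star across both locus groups plus background edges.

    The hub is connected to ``hub_neighbors_per_group`` genes in each locus
    group; ``background_edges`` further edges are sampled uniformly over
    non-hub gene pairs without duplicates or self-loops.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = sorted(truth.regulator)
    non_hub = [g for g in genes if g != truth.hub_gene_id]
    n_possible = len(non_hub) * (len(non_hub) - 1) // 2
    if config.background_edges > n_possible:
        raise ValidationError(
            f"background_edges={config.background_edges} exceeds the "
            f"{n_possible} possible non-hub pairs"
        )
    edges = list(truth.planted_edges)
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < config.background_edges:
        i, j = rng.integers(0, len(non_hub), size=2)
        if i == j:
            continue
        a, b = sorted((non_hub[i], non_hub[j]))
        chosen.add((a, b))
    edges.extend(sorted(chosen))
    return PpiNetwork.from_edges(edges)


def simulate_panel(config: CrossConfig):
    """Convenience wrapper: full synthetic panel in one call."""
    genotypes, gmap = simulate_cross(config)
    expr, annotation, trait, truth = simulate_expression_and_trait(
        genotypes, gmap, config
    )
    ppi = plant_network(truth, config)
    return genotypes, gmap, expr, annotation, trait, truth, ppi


def with_seed(config: CrossConfig, seed: int) -> CrossConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
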