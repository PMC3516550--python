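"""Reproducible recovery and calibration experiments on synthetic panels.

These are the package's release-gate experiments: each one simulates data
under the default study conditions, runs the relevant pipeline stage(s), and
measures a recovery or calibration statistic.  They are deliberately scaled
to run on a single CPU in minutes (250 mice, a 5x90 cM genome, 200-1000
permutations) — see the methods note for the problem sizes used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import kstest

from .causality import classify_triplet
from .model import ExpressionMatrix, TraitVector, ValidationError
from .network import CrossGroupNetwork
from .pipeline import analyze_panel
from .qtl import genomewide_threshold, lod_scan_matrix, scan_trait
from .scoring import permutation_pvalues
from .simulate import CrossConfig, simulate_cross, simulate_panel, with_seed


# ----------------------------------------------------------- hub recovery

@dataclass
class HubRecoveryResult:
    n_replicates: int
    n_rank1: int
    n_min_pvalue: int
    hub_ranks: list
    hub_pvalues: list
    hub_ties: list
    hub_corrs: list

    @property
    def rank1_fraction(self) -> float:
        return self.n_rank1 / self.n_replicates


def hub_recovery(
    n_replicates: int = 20,
    base_seed: int = 0,
    config: Optional[CrossConfig] = None,
    n_perm_tie: int = 200,
    n_perm_threshold: int = 200,
) -> HubRecoveryResult:
    """Scaled-down analogue of the full study: does the planted hub rank 1?

    For each replicate the entire pipeline runs from scratch (trait scan,
    top-two locus selection, eQTL overlap, causal/reactive filter, cross
    network, TIE ranking with a permutation null) and we record the planted
    hub's rank, TIE permutation p-value and expression-trait correlation.
    """
    config = config or CrossConfig()
    ranks, pvals, ties, corrs = [], [], [], []
    min_p = 1.0 / (n_perm_tie + 1.0)
    for rep in range(n_replicates):
        cfg = with_seed(config, base_seed + rep)
        genotypes, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        result = analyze_panel(
            genotypes, gmap, expr, annot, trait, ppi,
            n_perm_threshold=n_perm_threshold,
            n_perm_tie=n_perm_tie,
            seed=cfg.seed,
        )
        tab = result.rank
        row = tab[tab["gene"] == truth.hub_gene_id]
        if row.empty:
            ranks.append(np.inf)
            pvals.append(1.0)
            ties.append(0.0)
        else:
            ranks.append(int(row["rank"].iloc[0]))
            pvals.append(float(row["p_value"].iloc[0]))
            ties.append(float(row["tie_score"].iloc[0]))
        corrs.append(truth.realized["hub_trait_corr"])
    n_rank1 = sum(1 for r, t in zip(ranks, ties) if r == 1 and t > 0)
    n_min_p = sum(1 for p in pvals if abs(p - min_p) < 1e-12)
    return HubRecoveryResult(
        n_replicates=n_replicates,
        n_rank1=n_rank1,
        n_min_pvalue=n_min_p,
        hub_ranks=ranks,
        hub_pvalues=pvals,
        hub_ties=ties,
        hub_corrs=corrs,
    )


# ------------------------------------------------- conditional-scan analogue

def conditional_drop(
    n_replicates: int = 20,
    base_seed: int = 0,
    config: Optional[CrossConfig] = None,
    n_perm_threshold: int = 200,
) -> dict:
    """Does conditioning on hub expression abolish both trait QTLs?

    Per replicate: scan the trait, locate the two locus peaks, rescan with
    hub expression as a covariate, and test whether the conditional LOD at
    both peak markers falls below the genome-wide threshold.
    """
    config = config or CrossConfig()
    n_dropped = 0
    details = []
    for rep in range(n_replicates):
        cfg = with_seed(config, base_seed + rep)
        genotypes, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        threshold = genomewide_threshold(
            genotypes, gmap, trait, n_perm=n_perm_threshold, alpha=0.05, seed=cfg.seed
        )
        hub_expr = expr.gene_values(truth.hub_gene_id)
        # align hub expression to the genotype panel order
        order = {m: j for j, m in enumerate(expr.mice)}
        cov = np.array([hub_expr[order[m]] for m in genotypes.mice])
        cond = scan_trait(genotypes, gmap, trait, covariate=cov)
        m1 = gmap.nearest_marker(*cfg.locus1)
        m2 = gmap.nearest_marker(*cfg.locus2)
        lods = {
            m: float(cond.table.loc[cond.table["marker"] == m, "lod"].iloc[0])
            for m in (m1, m2)
        }
        dropped = all(v < threshold for v in lods.values())
        n_dropped += dropped
        details.append({"threshold": threshold, "conditional_lods": lods})
    return {
        "n_replicates": n_replicates,
        "n_dropped": n_dropped,
        "fraction": n_dropped / n_replicates,
        "details": details,
    }


# ------------------------------------------------------ causality calibration

def simulate_triplet(
    model: str,
    n: int,
    rng: np.random.Generator,
    eqtl_effect: float = 1.0,
    downstream_effect: float = 0.7,
    noise_sd: float = 1.0,
):
    """One synthetic (locus, gene, trait) triplet under a generating model."""
    codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.25, 0.5, 0.25])
    x = (codes - 1.0) / np.sqrt(0.5)
    e = lambda: noise_sd * rng.standard_normal(n)
    if model == "causal":
        g = eqtl_effect * x + e()
        t = downstream_effect * g + e()
    elif model == "reactive":
        t = eqtl_effect * x + e()
        g = downstream_effect * t + e()
    elif model == "independent":
        g = eqtl_effect * x + e()
        t = downstream_effect * x + e()
    else:
        raise ValidationError(f"unknown generating model {model!r}")
    return codes, g, t


def causality_accuracy(
    n: int = 250,
    n_replicates: int = 100,
    seed: int = 0,
    eqtl_effect: float = 1.0,
    downstream_effect: float = 0.7,
) -> dict[str, float]:
    """Fraction of correct labels per generating model."""
    rng = np.random.default_rng(seed)
    out = {}
    for model in ("causal", "reactive", "independent"):
        hits = 0
        for _ in range(n_replicates):
            codes, g, t = simulate_triplet(
                model, n, rng, eqtl_effect, downstream_effect
            )
            call = classify_triplet(codes, g, t)
            hits += call.label == model
        out[model] = hits / n_replicates
    return out


# ------------------------------------------------------------ FWE calibration

def fwe_calibration(
    n_replicates: int = 200,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    config: Optional[CrossConfig] = None,
) -> dict:
    """Family-wise error of the permutation genome-wide threshold.

    One genotype panel is simulated; for each replicate an independent null
    trait is drawn, its own permutation threshold computed, and we record
    whether the null scan's maximum LOD exceeds it.  The returned rate
    should sit near ``alpha``.
    """
    config = config or CrossConfig()
    genotypes, gmap = simulate_cross(config)
    rng = np.random.default_rng(seed)
    n = len(genotypes.mice)
    exceed = 0
    for _ in range(n_replicates):
        y = rng.standard_normal(n)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        big = np.column_stack([y, y[idx].T])  # observed + permutations
        maxima = lod_scan_matrix(genotypes.codes, big).max(axis=0)
        obs, perm_max = maxima[0], np.sort(maxima[1:])[::-1]
        k = min(max(int(np.floor(alpha * (n_perm + 1))), 1), n_perm)
        exceed += obs >= perm_max[k - 1]
    return {
        "n_replicates": n_replicates,
        "n_exceed": int(exceed),
        "rate": exceed / n_replicates,
        "alpha": alpha,
    }


# --------------------------------------------------------- TIE null p-values

def tie_null_ks(
    n_genes_per_group: int = 100,
    n_mice: int = 250,
    edges_per_gene: int = 6,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """KS statistic of TIE permutation p-values against U(0,1) under the null.

    Expression and trait are pure noise; the cross network links every
    group-1 gene to ``edges_per_gene`` random group-2 partners, so most genes
    clear the degree-5 rule and are scored.
    """
    rng = np.random.default_rng(seed)
    g1 = [f"a{i:03d}" for i in range(n_genes_per_group)]
    g2 = [f"b{i:03d}" for i in range(n_genes_per_group)]
    edges = set()
    for gene in g1:
        partners = rng.choice(n_genes_per_group, size=edges_per_gene, replace=False)
        for j in partners:
            edges.add(tuple(sorted((gene, g2[j]))))
    network = CrossGroupNetwork(
        group1=frozenset(g1), group2=frozenset(g2), edges=frozenset(edges)
    )
    genes = g1 + g2
    mice = [f"M{i:04d}" for i in range(n_mice)]
    expr = ExpressionMatrix(
        genes=genes, mice=mice, values=rng.standard_normal((len(genes), n_mice))
    )
    trait = TraitVector(mice=mice, values=rng.standard_normal(n_mice), name="null")
    ties, pvals = permutation_pvalues(
        network, expr, trait, n_perm=n_perm, seed=seed + 1
    )
    deg = network.degree
    scored = np.array([pvals[g] for g in genes if deg[g] >= 5])
    stat = kstest(scored, "uniform").statistic
    return {"n_scored": int(scored.size), "ks_statistic": float(stat)}
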