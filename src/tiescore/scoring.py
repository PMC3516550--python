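"""Interaction Potential, TIPC and TIE scoring with permutation p-values.

For a pair of interacting proteins, the Interaction Potential (IP) in mouse
``m`` combines the two genes' expression after min-max normalization across
the panel:

    E~_{g,m} = (E_{g,m} - min_m E_g) / (max_m E_g - min_m E_g)
    IP_{i,j,m} = E~_{i,m} * E~_{j,m}                 (mass-action product)

The product form follows the diffusion-limited association rationale: the
encounter rate of two species is proportional to the product of their
concentrations, so halving either partner's expression halves the pair's
interaction potential.  Alternative forms (min, geometric mean) are
selectable.

TIPC (Trait-IP Correlation) is the Pearson correlation between an edge's IP
profile and the clinical trait across mice.  The TIE (Trait-Interaction-
Expression) score of a gene with cross-network degree n >= 5 is the mean of
|TIPC| over its incident edges; genes with fewer than 5 interactions get TIE
exactly 0 (too few edges make the average unstable).  The absolute value
matters: a strong negative regulator is as informative as a positive one.

Significance: each gene's expression row is shuffled across mice
independently, all TIE scores are recomputed, and the per-gene empirical
p-value is (1 + #{permutations with TIE_perm >= TIE_obs}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, TraitVector, ValidationError
from .network import CrossGroupNetwork

logger = logging.getLogger("tiescore")

MIN_DEGREE = 5
_MIN_COMPLETE = 3

IP_FORMS = ("product", "min", "geomean")


@dataclass
class NormalizedExpression:
    """Min-max-normalized expression in [0, 1]; constant genes excluded."""

    genes: list
    mice: list
    values: np.ndarray  # genes x mice in [0, 1] (NaN where missing)
    excluded: list  # constant genes, flagged and left out of scoring

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(str(gene))]


@dataclass
class EdgeProfile:
    """Per-edge IP profile and its trait correlation."""

    edge: tuple
    ip: np.ndarray
    tipc: float
    n_complete: int


@dataclass
class TieRecord:
    """One row of the ranking table."""

    gene_id: str
    n_interactions: int
    tie: float
    p_value: float
    expr_trait_corr: float


def normalize_expression(expression: ExpressionMatrix) -> NormalizedExpression:
    """Scale each gene to [0, 1] by its panel-wide min and max."""
    vals = expression.values
    lo = np.nanmin(vals, axis=1, keepdims=True)
    hi = np.nanmax(vals, axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = (vals - lo) / span
    norm[constant] = np.nan
    excluded = [g for g, c in zip(expression.genes, constant) if c]
    if excluded:
        logger.warning("excluding %d constant genes from scoring", len(excluded))
    return NormalizedExpression(
        genes=list(expression.genes),
        mice=list(expression.mice),
        values=norm,
        excluded=excluded,
    )


def _combine(a: np.ndarray, b: np.ndarray, form: str) -> np.ndarray:
    if form == "product":
        return a * b
    if form == "min":
        return np.minimum(a, b)
    if form == "geomean":
        return np.sqrt(a * b)
    raise ValidationError(f"unknown IP form {form!r}; choose from {IP_FORMS}")


def interaction_potential(
    edge: tuple, norm: NormalizedExpression, form: str = "product"
) -> np.ndarray:
    """Per-mouse IP vector for one edge; NaN where either gene is missing."""
    a, b = edge
    return _combine(norm.row(a), norm.row(b), form)


def tipc(edge_ip: np.ndarray, trait: np.ndarray) -> float:
    """Pearson correlation of an edge's IP profile with the trait.

    Uses pairwise-complete observations; with fewer than 3 complete pairs or
    a constant IP/trait on the complete set, returns 0 (flagged, not
    dropped, so gene degrees stay stable).
    """
    ip = np.asarray(edge_ip, dtype=float)
    t = np.asarray(trait, dtype=float)
    keep = np.isfinite(ip) & np.isfinite(t)
    if keep.sum() < _MIN_COMPLETE:
        logger.warning("TIPC undefined (<3 complete pairs); using 0")
        return 0.0
    ip, t = ip[keep], t[keep]
    if np.ptp(ip) == 0 or np.ptp(t) == 0:
        return 0.0
    return float(np.corrcoef(ip, t)[0, 1])


def _edge_arrays(network: CrossGroupNetwork, norm: NormalizedExpression):
    index = {g: i for i, g in enumerate(norm.genes)}
    edges = sorted(e for e in network.edges if e[0] in index and e[1] in index)
    ei = np.array([index[a] for a, _ in edges], dtype=int)
    ej = np.array([index[b] for _, b in edges], dtype=int)
    return edges, ei, ej


def _all_tipc(
    values: np.ndarray,
    ei: np.ndarray,
    ej: np.ndarray,
    trait: np.ndarray,
    form: str,
) -> np.ndarray:
    """Vectorized TIPC for all edges at once (complete data fast path)."""
    ip = _combine(values[ei], values[ej], form)  # edges x mice
    ipc = ip - ip.mean(axis=1, keepdims=True)
    tc = trait - trait.mean()
    denom = np.sqrt((ipc**2).sum(axis=1) * (tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ipc @ tc) / denom
    return np.where(np.isfinite(r), r, 0.0)


def edge_profiles(
    network: CrossGroupNetwork,
    norm: NormalizedExpression,
    trait_values: np.ndarray,
    form: str = "product",
) -> dict[tuple, EdgeProfile]:
    """IP profile and TIPC for every cross-network edge with expression."""
    trait_values = np.asarray(trait_values, dtype=float)
    out = {}
    for edge in sorted(network.edges):
        if edge[0] not in norm.genes or edge[1] not in norm.genes:
            continue
        ip = interaction_potential(edge, norm, form)
        keep = np.isfinite(ip) & np.isfinite(trait_values)
        out[edge] = EdgeProfile(
            edge=edge,
            ip=ip,
            tipc=tipc(ip, trait_values),
            n_complete=int(keep.sum()),
        )
    return out


def tie_scores(
    network: CrossGroupNetwork,
    edge_tipc: dict,
    min_degree: int = MIN_DEGREE,
    exponent: float = 1.0,
) -> dict[str, float]:
    """Per-gene TIE: mean |TIPC| over incident edges, 0 below ``min_degree``.

    The degree is the gene's degree in the cross-group network (counting all
    its edges, including those whose TIPC is 0).
    """
    deg = network.degree
    acc: dict[str, float] = {g: 0.0 for g in deg}
    for (a, b), t in edge_tipc.items():
        val = np.abs(t) ** exponent
        acc[a] += val
        acc[b] += val
    return {
        g: (acc[g] / deg[g] if deg[g] >= min_degree else 0.0) for g in deg
    }


def _prepare(
    network: CrossGroupNetwork,
    expression: ExpressionMatrix,
    trait: TraitVector,
):
    norm = normalize_expression(expression)
    t = trait.reindex(expression.mice)
    return norm, t


def _tie_from_values(
    values, ei, ej, edges, trait_values, network, min_degree, form, exponent
):
    r = _all_tipc(values, ei, ej, trait_values, form)
    edge_tipc = dict(zip(edges, r))
    return tie_scores(network, edge_tipc, min_degree, exponent)


def permutation_pvalues(
    network: CrossGroupNetwork,
    expression: ExpressionMatrix,
    trait: TraitVector,
    n_perm: int = 1000,
    seed: int = 0,
    min_degree: int = MIN_DEGREE,
    form: str = "product",
    exponent: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Observed TIE scores and per-gene empirical permutation p-values.

    Each permutation shuffles every gene's expression across mice
    independently, destroying both gene-gene and gene-trait structure while
    preserving each gene's marginal distribution (and hence its min-max
    normalization).  Genes below ``min_degree`` get p = 1 by convention.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    norm, trait_values = _prepare(network, expression, trait)
    keep = np.isfinite(trait_values)
    values = norm.values[:, keep]
    trait_values = trait_values[keep]
    values = np.nan_to_num(values, nan=0.5)  # rare missing cells mid-scale
    edges, ei, ej = _edge_arrays(network, norm)

    observed = _tie_from_values(
        values, ei, ej, edges, trait_values, network, min_degree, form, exponent
    )
    rng = np.random.default_rng(seed)
    exceed = {g: 0 for g in observed}
    for _ in range(n_perm):
        shuffled = rng.permuted(values, axis=1)
        perm_tie = _tie_from_values(
            shuffled, ei, ej, edges, trait_values, network, min_degree, form, exponent
        )
        for g, v in perm_tie.items():
            if v >= observed[g]:
                exceed[g] += 1
    deg = network.degree
    pvals = {
        g: (1.0 if deg[g] < min_degree else (1.0 + exceed[g]) / (n_perm + 1.0))
        for g in observed
    }
    return observed, pvals


def expression_trait_correlation(
    expression: ExpressionMatrix, trait: TraitVector
) -> dict[str, float]:
    """Pearson correlation of each gene's raw expression with the trait."""
    t = trait.reindex(expression.mice)
    out = {}
    for g, row in zip(expression.genes, expression.values):
        keep = np.isfinite(row) & np.isfinite(t)
        if keep.sum() < _MIN_COMPLETE or np.ptp(row[keep]) == 0 or np.ptp(t[keep]) == 0:
            out[g] = float("nan")
        else:
            out[g] = float(np.corrcoef(row[keep], t[keep])[0, 1])
    return out


def build_records(
    network: CrossGroupNetwork,
    ties: dict[str, float],
    pvals: dict[str, float],
    corr: dict[str, float],
) -> list[TieRecord]:
    deg = network.degree
    return [
        TieRecord(
            gene_id=g,
            n_interactions=deg[g],
            tie=float(ties.get(g, 0.0)),
            p_value=float(pvals.get(g, 1.0)),
            expr_trait_corr=float(corr.get(g, float("nan"))),
        )
        for g in sorted(deg)
    ]


def rank_table(records: Sequence[TieRecord]) -> pd.DataFrame:
    """Ranking table: TIE descending, ties broken by degree then gene id."""
    rows = sorted(
        records, key=lambda r: (-r.tie, -r.n_interactions, r.gene_id)
    )
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "gene": [r.gene_id for r in rows],
            "n_interactions": [r.n_interactions for r in rows],
            "tie_score": [r.tie for r in rows],
            "p_value": [r.p_value for r in rows],
            "expr_trait_corr": [r.expr_trait_corr for r in rows],
        }
    )
    return frame


def score_network(
    network: CrossGroupNetwork,
    expression: ExpressionMatrix,
    trait: TraitVector,
    n_perm: int = 1000,
    seed: int = 0,
    min_degree: int = MIN_DEGREE,
    form: str = "product",
    exponent: float = 1.0,
) -> pd.DataFrame:
    """One-call scoring: TIE, permutation p and trait correlation per gene."""
    ties, pvals = permutation_pvalues(
        network, expression, trait, n_perm, seed, min_degree, form, exponent
    )
    corr = expression_trait_correlation(expression, trait)
    return rank_table(build_records(network, ties, pvals, corr))
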