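"""Causal / reactive / independent classification of (locus, gene, trait).

For a locus L (genotype factor), a gene expression G and a clinical trait T,
three Gaussian graphical models are fit by maximum likelihood and scored by
BIC:

* causal      L -> G -> T : ll(G | L) + ll(T | G)
* reactive    L -> T -> G : ll(T | L) + ll(G | T)
* independent L -> G, L -> T with a residual-correlation parameter —
  the saturated bivariate-Gaussian-given-L model, so pleiotropy without
  mediation is not misread as causation.

The label is the minimum-BIC model.  The causal and reactive models each
spend 2k + 4 parameters (k genotype levels: group means + variance for the
locus child, slope/intercept/variance for the downstream regression); the
independent model spends 2k + 3 (two sets of group means plus a full 2x2
residual covariance).  BIC ties below 1e-9 are conservatively labeled
independent.  This likelihood/BIC formulation is a fully specified,
deterministic variant of the classic three-model causality test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))
_TIE_EPS = 1e-9
MIN_TRIPLET_OBS = 30

LABELS = ("causal", "reactive", "independent")


@dataclass
class CausalCall:
    """Result of one triplet classification."""

    gene_id: str
    locus: str
    scores: dict  # model label -> BIC
    label: str
    margin: float  # runner-up BIC minus best BIC (>= 0)


def _group_residuals(x: np.ndarray, level_codes: np.ndarray, n_levels: int):
    """Residuals after removing per-genotype-class means."""
    resid = x.astype(float).copy()
    for lev in range(n_levels):
        sel = level_codes == lev
        resid[sel] -= resid[sel].mean()
    return resid


def _ll_gaussian(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (_LOG_2PI + np.log(sigma2) + 1.0)


def _ll_child_of_factor(x, level_codes, n_levels) -> float:
    resid = _group_residuals(x, level_codes, n_levels)
    return _ll_gaussian(float(resid @ resid), x.size)


def _ll_simple_regression(y, x) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc)
    beta = float(xc @ yc) / denom if denom > 0 else 0.0
    resid = yc - beta * xc
    return _ll_gaussian(float(resid @ resid), y.size)


def classify_triplet(
    locus_genotypes: np.ndarray,
    gene_expr: np.ndarray,
    trait: np.ndarray,
    gene_id: str = "gene",
    locus: str = "locus",
) -> CausalCall:
    """Classify one (locus, gene, trait) triplet by BIC model selection.

    ``locus_genotypes`` are per-mouse codes {0, 1, 2} (NaN = missing); the
    three vectors are aligned by position and reduced to complete cases.
    """
    g = np.asarray(gene_expr, dtype=float)
    t = np.asarray(trait, dtype=float)
    loc = np.asarray(locus_genotypes, dtype=float)
    keep = np.isfinite(g) & np.isfinite(t) & np.isfinite(loc)
    g, t, loc = g[keep], t[keep], loc[keep]
    n = g.size
    if n < MIN_TRIPLET_OBS:
        raise ValidationError(
            f"need >= {MIN_TRIPLET_OBS} complete triplet observations, got {n}"
        )
    if np.ptp(g) == 0:
        raise ValidationError("zero-variance gene expression")
    if np.ptp(t) == 0:
        raise ValidationError("zero-variance trait")
    levels = np.unique(loc)
    if levels.size < 2:
        raise ValidationError("monomorphic locus")
    level_codes = np.searchsorted(levels, loc)
    k = levels.size
    log_n = np.log(n)

    # causal: L -> G -> T
    ll_causal = _ll_child_of_factor(g, level_codes, k) + _ll_simple_regression(t, g)
    bic_causal = (k + 1 + 3) * log_n - 2.0 * ll_causal

    # reactive: L -> T -> G
    ll_reactive = _ll_child_of_factor(t, level_codes, k) + _ll_simple_regression(g, t)
    bic_reactive = (k + 1 + 3) * log_n - 2.0 * ll_reactive

    # independent: saturated bivariate Gaussian given L (residual correlation)
    rg = _group_residuals(g, level_codes, k)
    rt = _group_residuals(t, level_codes, k)
    cov = np.array([[rg @ rg, rg @ rt], [rg @ rt, rt @ rt]]) / n
    det = float(np.linalg.det(cov))
    det = max(det, 1e-300)
    ll_indep = -0.5 * n * (2.0 * _LOG_2PI + np.log(det) + 2.0)
    bic_indep = (2 * k + 3) * log_n - 2.0 * ll_indep

    scores = {
        "causal": float(bic_causal),
        "reactive": float(bic_reactive),
        "independent": float(bic_indep),
    }
    ordered = sorted(scores.items(), key=lambda kv: kv[1])
    best, runner = ordered[0], ordered[1]
    margin = runner[1] - best[1]
    label = "independent" if margin < _TIE_EPS else best[0]
    return CausalCall(
        gene_id=gene_id, locus=locus, scores=scores, label=label, margin=float(margin)
    )


def filter_causal_reactive(calls: Sequence[CausalCall]) -> dict[str, set]:
    """Per-locus gene sets retaining only causal or reactive genes.

    Genes labeled independent are removed: linked to the same locus as the
    trait, but not supported as part of the trait's regulatory chain.
    """
    out: dict[str, set] = {}
    for call in calls:
        out.setdefault(call.locus, set())
        if call.label in ("causal", "reactive"):
            out[call.locus].add(call.gene_id)
    return out
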