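"""Transcriptome-wide eQTL scans, cis/trans calls and trait-QTL overlap.

Every expressed gene is scanned as a quantitative trait; chromosome-wise
LOD peaks above ``lod_min`` become :class:`EqtlCall` records (a gene may
link to several loci).  A call is *cis* when the peak lies within a genomic
window (default 10 Mb, boundary inclusive) of the gene's own position on the
same chromosome, *trans* otherwise.  Calls are then intersected with the
clinical-trait QTL support intervals, and a permutation scheme estimates a
false-discovery rate for the per-locus overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    GenotypeMatrix,
    ValidationError,
)
from .qtl import LodCurve, QtlInterval, lod_scan_matrix

logger = logging.getLogger("tiescore")

CIS_WINDOW_BP = 10_000_000


@dataclass
class EqtlCall:
    """One chromosome-wise eQTL peak for one gene."""

    gene_id: str
    tissue: str
    peak_marker_id: str
    chromosome: str
    position_cM: float
    lod: float
    is_cis: Optional[bool] = None
    overlapped_locus: Optional[str] = None  # none | locus1 | locus2 | both


def _aligned_expression(
    genotypes: GenotypeMatrix, expression: ExpressionMatrix
) -> tuple[np.ndarray, list[str]]:
    """Expression columns reordered to the genotyped mice (must be subset)."""
    missing = set(expression.mice) - set(genotypes.mice)
    if missing:
        raise ValidationError(
            f"expression mice not in genotyped panel: {sorted(missing)[:3]}"
        )
    order = [m for m in genotypes.mice if m in set(expression.mice)]
    col = {m: j for j, m in enumerate(expression.mice)}
    values = expression.values[:, [col[m] for m in order]]
    return values, order


def scan_all_genes(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    expression: ExpressionMatrix,
    lod_min: float,
) -> list[EqtlCall]:
    """Chromosome-wise eQTL peaks with LOD >= ``lod_min`` for every gene.

    Constant expression rows are skipped with a warning.  Genes with missing
    expression values are scanned on their complete cases.
    """
    values, order = _aligned_expression(genotypes, expression)
    keep_rows = np.where([np.nanstd(row) > 0 for row in values])[0]
    skipped = len(expression.genes) - keep_rows.size
    if skipped:
        logger.warning("skipping %d constant expression rows", skipped)
    sub_idx = [genotypes.mice.index(m) for m in order]
    codes = genotypes.codes[sub_idx]

    complete = ~np.isnan(values[keep_rows]).any(axis=1)
    lods = np.zeros((gmap.n_markers, keep_rows.size))
    if complete.any():
        lods[:, complete] = lod_scan_matrix(codes, values[keep_rows][complete].T)
    for k in np.where(~complete)[0]:
        row = values[keep_rows[k]]
        ok = np.isfinite(row)
        lods[:, k] = lod_scan_matrix(codes[ok], row[ok])[:, 0]

    chrom = gmap.table["chromosome"].to_numpy()
    calls: list[EqtlCall] = []
    for c in gmap.chromosomes:
        rows = np.where(chrom == c)[0]
        sub = lods[rows]
        peak_pos = rows[np.argmax(sub, axis=0)]
        peak_lod = sub.max(axis=0)
        for k in np.where(peak_lod >= lod_min)[0]:
            j = peak_pos[k]
            calls.append(
                EqtlCall(
                    gene_id=expression.genes[keep_rows[k]],
                    tissue=expression.tissue,
                    peak_marker_id=gmap.table.loc[j, "marker"],
                    chromosome=c,
                    position_cM=float(gmap.table.loc[j, "cM"]),
                    lod=float(peak_lod[k]),
                )
            )
    return calls


def classify_cis(
    call: EqtlCall,
    annotation: GeneAnnotation,
    gmap: GeneticMap,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> bool:
    """True iff the peak is within ``cis_window_bp`` of the gene (inclusive)."""
    gene_chrom, gene_bp = annotation.position(call.gene_id)
    if gene_chrom != call.chromosome:
        return False
    marker_bp = int(gmap.marker_row(call.peak_marker_id)["bp"])
    return abs(gene_bp - marker_bp) <= cis_window_bp


def annotate_cis(
    calls: Sequence[EqtlCall],
    annotation: GeneAnnotation,
    gmap: GeneticMap,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> list[EqtlCall]:
    return [
        replace(c, is_cis=classify_cis(c, annotation, gmap, cis_window_bp))
        for c in calls
    ]


def overlap_with_trait_qtl(
    calls: Sequence[EqtlCall],
    trait_intervals: Sequence[QtlInterval],
) -> list[EqtlCall]:
    """Set ``overlapped_locus`` on each call (gene-level label).

    ``trait_intervals`` is ordered (locus1, locus2).  A peak overlaps a locus
    when it lies on the interval's chromosome with cM inside [start, end]
    (inclusive).  A gene with qualifying peaks in both intervals is labeled
    ``both`` on all of its overlapping calls.
    """
    labels = ("locus1", "locus2")
    per_gene: dict[str, set[str]] = {}
    hit: list[Optional[str]] = []
    for call in calls:
        found = None
        for label, interval in zip(labels, trait_intervals):
            if interval is not None and interval.contains(
                call.chromosome, call.position_cM
            ):
                found = label
                break
        hit.append(found)
        if found:
            per_gene.setdefault(call.gene_id, set()).add(found)
    out = []
    for call, found in zip(calls, hit):
        loci = per_gene.get(call.gene_id, set())
        if found is None:
            label = "none"
        elif len(loci) == 2:
            label = "both"
        else:
            label = found
        out.append(replace(call, overlapped_locus=label))
    return out


def locus_gene_sets(calls: Sequence[EqtlCall]) -> tuple[set, set]:
    """Gene sets with qualifying peaks inside the locus-1 / locus-2 intervals."""
    g1 = {c.gene_id for c in calls if c.overlapped_locus in ("locus1", "both")}
    g2 = {c.gene_id for c in calls if c.overlapped_locus in ("locus2", "both")}
    return g1, g2


def _overlap_counts(
    codes: np.ndarray,
    gmap: GeneticMap,
    values: np.ndarray,
    trait_intervals: Sequence[QtlInterval],
    lod_min: float,
) -> np.ndarray:
    """#genes whose chromosome-wise peak falls in each interval (fast path)."""
    lods = lod_scan_matrix(codes, values.T)  # markers x genes
    chrom = gmap.table["chromosome"].to_numpy()
    cms = gmap.table["cM"].to_numpy()
    counts = np.zeros(len(trait_intervals), dtype=int)
    for i, interval in enumerate(trait_intervals):
        rows = np.where(chrom == interval.chromosome)[0]
        sub = lods[rows]
        peak_k = np.argmax(sub, axis=0)
        peak_lod = sub.max(axis=0)
        peak_cm = cms[rows[peak_k]]
        inside = (peak_cm >= interval.start_cM) & (peak_cm <= interval.end_cM)
        counts[i] = int((inside & (peak_lod >= lod_min)).sum())
    return counts


def count_fdr(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    expression: ExpressionMatrix,
    trait_intervals: Sequence[QtlInterval],
    lod_min: float,
    n_perm: int = 20,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Observed per-locus eQTL overlap counts with a permutation FDR.

    The whole expression matrix is permuted by shuffling mouse labels jointly
    across all genes — preserving the gene-gene correlation structure while
    breaking genotype linkage.  FDR(locus) = mean permuted count / observed
    count (NaN when the observed count is zero).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    values, order = _aligned_expression(genotypes, expression)
    ok = np.where([np.nanstd(row) > 0 for row in values])[0]
    values = np.nan_to_num(values[ok], nan=0.0)
    sub_idx = [genotypes.mice.index(m) for m in order]
    codes = genotypes.codes[sub_idx]

    observed = _overlap_counts(codes, gmap, values, trait_intervals, lod_min)
    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((n_perm, len(trait_intervals)))
    for b in range(n_perm):
        perm = rng.permutation(values.shape[1])
        perm_counts[b] = _overlap_counts(
            codes, gmap, values[:, perm], trait_intervals, lod_min
        )
    out = {}
    for i, label in enumerate(["locus1", "locus2"][: len(trait_intervals)]):
        obs = int(observed[i])
        fdr = float(perm_counts[:, i].mean() / obs) if obs > 0 else float("nan")
        out[label] = {"observed": obs, "expected_null": float(perm_counts[:, i].mean()), "fdr": fdr}
    return out
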