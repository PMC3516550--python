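"""eQTL scans, cis/trans classification, trait-QTL overlap and count FDR."""

import numpy as np
import pandas as pd
import pytest

from tiescore.eqtl import (
    EqtlCall,
    annotate_cis,
    classify_cis,
    count_fdr,
    locus_gene_sets,
    overlap_with_trait_qtl,
    scan_all_genes,
)
from tiescore.model import GeneAnnotation, GeneticMap, ValidationError
from tiescore.qtl import QtlInterval, genomewide_threshold
from tiescore.simulate import CrossConfig, simulate_panel, with_seed

from conftest import annotation_for


def _call(gene="g1", chrom="2", cm=70.0, marker="mk", lod=5.0):
    return EqtlCall(
        gene_id=gene, tissue="islet", peak_marker_id=marker,
        chromosome=chrom, position_cM=cm, lod=lod,
    )


class TestCisClassification:
    def _map_with(self, marker_bp, chrom="2"):
        return GeneticMap(
            pd.DataFrame(
                {"marker": ["mk"], "chromosome": [chrom], "cM": [10.0], "bp": [marker_bp]}
            )
        )

    def test_within_10mb_same_chromosome_is_cis(self):
        gmap = self._map_with(55_000_000)
        annot = GeneAnnotation(
            pd.DataFrame({"gene": ["g1"], "chromosome": ["2"], "bp": [50_000_000]})
        )
        assert classify_cis(_call(), annot, gmap) is True

    def test_other_chromosome_is_trans(self):
        gmap = self._map_with(50_000_000, chrom="5")
        annot = GeneAnnotation(
            pd.DataFrame({"gene": ["g1"], "chromosome": ["2"], "bp": [50_000_000]})
        )
        assert classify_cis(_call(chrom="5"), annot, gmap) is False

    def test_boundary_exactly_10mb_is_cis(self):
        gmap = self._map_with(60_000_000)
        annot = GeneAnnotation(
            pd.DataFrame({"gene": ["g1"], "chromosome": ["2"], "bp": [50_000_000]})
        )
        assert classify_cis(_call(), annot, gmap) is True
        annot_far = GeneAnnotation(
            pd.DataFrame({"gene": ["g1"], "chromosome": ["2"], "bp": [49_999_999]})
        )
        assert classify_cis(_call(), annot_far, gmap) is False


class TestOverlap:
    interval = QtlInterval("2", 59.5, 82.5, "mk", 6.5)
    interval2 = QtlInterval("19", 25.0, 35.38, "mk2", 5.4)

    def _overlap(self, cm, chrom="2"):
        calls = overlap_with_trait_qtl(
            [_call(cm=cm, chrom=chrom)], [self.interval, self.interval2]
        )
        return calls[0].overlapped_locus

    def test_peak_inside_interval_overlaps(self):
        assert self._overlap(70.0) == "locus1"

    def test_peak_outside_interval_does_not(self):
        assert self._overlap(50.0) == "none"

    def test_boundary_inclusive(self):
        assert self._overlap(59.5) == "locus1"
        assert self._overlap(82.5) == "locus1"

    def test_gene_with_peaks_in_both_intervals_labeled_both(self):
        calls = overlap_with_trait_qtl(
            [_call(cm=70.0, chrom="2"), _call(cm=30.0, chrom="19")],
            [self.interval, self.interval2],
        )
        assert all(c.overlapped_locus == "both" for c in calls)
        g1, g2 = locus_gene_sets(calls)
        assert g1 == g2 == {"g1"}


class TestScanAllGenes:
    def test_planted_cis_gene_recovered(self):
        # strong cis effect: peak lands on the gene's own chromosome within
        # 10 cM of the truth in nearly every replicate
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = with_seed(CrossConfig(n_cis_genes=5, n_trans1_genes=0,
                                        n_trans2_genes=0, n_both_genes=0,
                                        n_null_genes=5), 700 + seed)
            geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
            calls = scan_all_genes(geno, gmap, expr, lod_min=3.0)
            calls = annotate_cis(calls, annot, gmap)
            ok = True
            for gene in [g for g, r in truth.regulator.items() if r == "cis"]:
                chrom, bp = annot.position(gene)
                true_cm = bp / cfg.bp_per_cM
                mine = [c for c in calls if c.gene_id == gene and c.chromosome == chrom
                        and abs(c.position_cM - true_cm) <= 10.0]
                ok &= bool(mine) and any(c.is_cis for c in mine)
            hits += ok
        assert hits >= 0.9 * n_seeds

    def test_noise_genes_rarely_exceed_genomewide_threshold(self):
        cfg = CrossConfig(seed=71, n_cis_genes=0, n_trans1_genes=0,
                          n_trans2_genes=0, n_both_genes=0, n_null_genes=100)
        geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        thr = genomewide_threshold(geno, gmap, trait, n_perm=200, seed=71)
        calls = scan_all_genes(geno, gmap, expr, lod_min=thr)
        null_genes = {g for g, r in truth.regulator.items() if r == "none"}
        flagged = {c.gene_id for c in calls} & null_genes
        assert len(flagged) / len(null_genes) <= 0.10

    def test_gene_linked_to_both_loci_gets_two_peaks(self):
        cfg = CrossConfig(seed=72, eqtl_effect=1.5, n_cis_genes=0,
                          n_trans1_genes=0, n_trans2_genes=0, n_both_genes=3,
                          n_null_genes=0)
        geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        calls = scan_all_genes(geno, gmap, expr, lod_min=3.0)
        for gene in [g for g in truth.regulator if g.startswith("tb_")]:
            chroms = {c.chromosome for c in calls if c.gene_id == gene}
            assert {"1", "2"} <= chroms

    def test_constant_gene_skipped(self, default_panel):
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        values = expr.values.copy()
        values[0] = 1.0  # constant row
        from tiescore.model import ExpressionMatrix

        flat = ExpressionMatrix(genes=expr.genes, mice=expr.mice, values=values)
        calls = scan_all_genes(geno, gmap, flat, lod_min=3.0)
        assert expr.genes[0] not in {c.gene_id for c in calls}


class TestCountFdr:
    intervals = [
        QtlInterval("1", 30.0, 60.0, "c1m015", 5.0),
        QtlInterval("2", 30.0, 60.0, "c2m015", 5.0),
    ]

    def test_null_panel_fdr_near_one(self):
        cfg = CrossConfig(seed=11, n_trans1_genes=0, n_trans2_genes=0,
                          n_both_genes=0, n_cis_genes=0, n_null_genes=150,
                          n_reactive1_genes=10, n_reactive2_genes=10,
                          locus_r2=(1e-10, 1e-10), gamma_hub=-1e-4,
                          reactive_effect=0.0)
        geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        out = count_fdr(geno, gmap, expr, self.intervals, lod_min=2.0,
                        n_perm=20, seed=1)
        for locus in out.values():
            if locus["observed"] > 0:
                assert locus["fdr"] > 0.4  # observed ~ expected under the null

    def test_planted_trans_band_has_low_fdr(self):
        cfg = CrossConfig(seed=12, n_trans1_genes=100, n_trans2_genes=0,
                          n_both_genes=0, n_cis_genes=0, n_null_genes=50)
        geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(cfg)
        out = count_fdr(geno, gmap, expr, self.intervals, lod_min=3.0,
                        n_perm=10, seed=3)
        assert out["locus1"]["observed"] >= 80
        assert out["locus1"]["fdr"] < 0.2

    def test_zero_permutations_rejected(self, default_panel):
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        with pytest.raises(ValidationError):
            count_fdr(geno, gmap, expr, self.intervals, lod_min=3.0, n_perm=0)


def test_cis_trans_partition_exhaustive(default_panel):
    geno, gmap, expr, annot, trait, truth, ppi = default_panel
    calls = scan_all_genes(geno, gmap, expr, lod_min=3.0)
    calls = annotate_cis(calls, annot, gmap)
    assert all(c.is_cis in (True, False) for c in calls)
    assert all(c.lod >= 3.0 for c in calls)
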