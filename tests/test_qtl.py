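"""Marker-regression scans against independent least-squares oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiescore.model import GeneticMap, GenotypeMatrix, TraitVector, ValidationError
from tiescore.qtl import (
    LodCurve,
    call_intervals,
    genomewide_threshold,
    scan_trait,
    select_top_loci,
    variance_explained,
)
from tiescore.simulate import CrossConfig, simulate_cross, simulate_panel, with_seed


def oracle_lod(codes_1m: np.ndarray, y: np.ndarray) -> float:
    """Brute-force LOD at one marker: both RSS via explicit normal equations."""
    keep = np.isfinite(codes_1m) & np.isfinite(y)
    g, yy = codes_1m[keep], y[keep]
    n = yy.size
    rss_null = float(((yy - yy.mean()) ** 2).sum())
    levels = np.unique(g)
    X = np.column_stack([(g == lev).astype(float) for lev in levels])
    beta = np.linalg.solve(X.T @ X, X.T @ yy)
    resid = yy - X @ beta
    rss_full = float(resid @ resid)
    if rss_full <= 0 or len(levels) <= 1:
        return 0.0
    return max(0.0, (n / 2.0) * np.log10(rss_null / rss_full))


def _trait_for(geno, values):
    return TraitVector(mice=list(geno.mice), values=np.asarray(values, float))


def test_scan_matches_oracle_on_printed_fixture(tiny_genotypes, tiny_map):
    y = np.array([3.1, 5.2, 0.4, 2.2, 4.4, 1.0, 2.9, 3.3, 0.1, 5.0, 2.5, 1.8])
    curve = scan_trait(tiny_genotypes, tiny_map, _trait_for(tiny_genotypes, y))
    for j, marker in enumerate(tiny_map.marker_ids):
        expected = oracle_lod(tiny_genotypes.codes[:, j], y)
        assert curve.table.loc[curve.table["marker"] == marker, "lod"].iloc[0] == pytest.approx(
            expected, abs=1e-8
        )


def test_scan_matches_oracle_on_random_panel():
    cfg = CrossConfig(seed=31, n_mice=40, chromosomes=(("1", 40.0, 8), ("2", 40.0, 8)))
    geno, gmap = simulate_cross(cfg)
    rng = np.random.default_rng(8)
    y = rng.standard_normal(40)
    # knock out some genotypes: complete-case handling must match the oracle
    codes = geno.codes.copy()
    codes[rng.random(codes.shape) < 0.1] = np.nan
    geno = GenotypeMatrix(mice=geno.mice, gmap=gmap, codes=codes)
    curve = scan_trait(geno, gmap, _trait_for(geno, y))
    for j in range(gmap.n_markers):
        assert curve.lod[j] == pytest.approx(oracle_lod(codes[:, j], y), abs=1e-8)


def test_monomorphic_marker_gets_lod_zero(tiny_map):
    codes = np.ones((12, 4))
    codes[:, 1] = np.repeat([0.0, 1.0, 2.0], 4)
    geno = GenotypeMatrix(mice=[f"M{i}" for i in range(12)], gmap=tiny_map, codes=codes)
    y = np.arange(12.0)
    curve = scan_trait(geno, tiny_map, _trait_for(geno, y))
    assert curve.lod[0] == 0.0
    assert curve.lod[2] == 0.0


def test_zero_variance_trait_rejected(tiny_genotypes, tiny_map):
    with pytest.raises(ValidationError, match="zero-variance"):
        scan_trait(tiny_genotypes, tiny_map, _trait_for(tiny_genotypes, np.ones(12)))


def test_constant_covariate_rejected(tiny_genotypes, tiny_map):
    y = np.arange(12.0)
    with pytest.raises(ValidationError, match="collinear"):
        scan_trait(
            tiny_genotypes, tiny_map, _trait_for(tiny_genotypes, y), covariate=np.ones(12)
        )


@settings(max_examples=20, deadline=None)
@given(
    scale=st.floats(min_value=0.01, max_value=100.0),
    shift=st.floats(min_value=-50.0, max_value=50.0),
)
def test_lod_invariant_under_affine_trait_transform(scale, shift):
    cfg = CrossConfig(seed=13, n_mice=30, chromosomes=(("1", 30.0, 6), ("2", 30.0, 6)))
    geno, gmap = simulate_cross(cfg)
    rng = np.random.default_rng(2)
    y = rng.standard_normal(30)
    base = scan_trait(geno, gmap, _trait_for(geno, y)).lod
    transformed = scan_trait(geno, gmap, _trait_for(geno, scale * y + shift)).lod
    np.testing.assert_allclose(base, transformed, atol=1e-8)


def test_independent_covariate_barely_moves_null_lod():
    cfg = CrossConfig(seed=41)
    geno, gmap = simulate_cross(cfg)
    rng = np.random.default_rng(41)
    y = rng.standard_normal(cfg.n_mice)
    cov = rng.standard_normal(cfg.n_mice)
    plain = scan_trait(geno, gmap, _trait_for(geno, y)).lod
    adjusted = scan_trait(geno, gmap, _trait_for(geno, y), covariate=cov).lod
    assert np.max(np.abs(plain - adjusted)) < 0.5


class TestThreshold:
    def test_deterministic_under_seed(self, default_panel):
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        a = genomewide_threshold(geno, gmap, trait, n_perm=100, seed=5)
        b = genomewide_threshold(geno, gmap, trait, n_perm=100, seed=5)
        assert a == b

    def test_alpha_one_returns_minimum_of_maxima(self, default_panel):
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        lo = genomewide_threshold(geno, gmap, trait, n_perm=100, alpha=1.0, seed=5)
        hi = genomewide_threshold(geno, gmap, trait, n_perm=100, alpha=0.05, seed=5)
        assert lo <= hi

    def test_few_permutations_warn(self, default_panel):
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        with pytest.warns(UserWarning, match="unstable"):
            genomewide_threshold(geno, gmap, trait, n_perm=50, seed=5)


class TestIntervals:
    def _curve(self, lods):
        table = pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(len(lods))],
                "chromosome": "1",
                "cM": np.arange(len(lods), dtype=float),
                "lod": lods,
            }
        )
        return LodCurve(table=table)

    def test_all_below_threshold_gives_empty_list(self):
        assert call_intervals(self._curve([0.5, 1.0, 0.2]), threshold=3.0) == []

    def test_single_marker_spike_degenerates_to_point(self):
        iv = call_intervals(self._curve([0.0, 6.0, 0.1]), threshold=3.0)
        assert len(iv) == 1
        assert iv[0].start_cM == iv[0].end_cM == 1.0
        assert iv[0].peak_marker_id == "m1"

    def test_two_locus_recovery(self):
        # strong two-locus trait: both support intervals found and contain
        # the true locus positions in nearly all replicates
        cfg = CrossConfig(locus_r2=(0.20, 0.15))
        hits = 0
        for seed in range(20):
            c = with_seed(cfg, 300 + seed)
            geno, gmap, expr, annot, trait, truth, ppi = simulate_panel(c)
            thr = genomewide_threshold(geno, gmap, trait, n_perm=200, seed=seed)
            curve = scan_trait(geno, gmap, trait)
            ivs = call_intervals(curve, thr)
            # the causal position is the marker nearest the nominal locus
            true_pos = [
                (locus[0], gmap.marker_row(gmap.nearest_marker(*locus))["cM"])
                for locus in (c.locus1, c.locus2)
            ]
            ok = len(ivs) == 2 and all(
                any(iv.contains(chrom, cm) for iv in ivs) for chrom, cm in true_pos
            )
            hits += ok
        assert hits >= 18  # >= 90% of replicates

    def test_select_top_loci_ignores_threshold(self):
        curve = self._curve([0.0, 2.0, 0.1])
        assert call_intervals(curve, threshold=3.0) == []
        top = select_top_loci(curve, k=1)
        assert len(top) == 1 and top[0].peak_marker_id == "m1"


class TestVarianceExplained:
    def test_trait_equal_to_genotype_gives_r2_one(self, tiny_genotypes, tiny_map):
        y = tiny_genotypes.codes[:, 0].copy()
        out = variance_explained(tiny_genotypes, _trait_for(tiny_genotypes, y), ["m1"])
        assert out["m1"] == pytest.approx(1.0, abs=1e-12)

    def test_null_trait_small_r2(self):
        cfg = CrossConfig(seed=51)
        geno, gmap = simulate_cross(cfg)
        rng = np.random.default_rng(51)
        y = rng.standard_normal(cfg.n_mice)
        m1 = gmap.nearest_marker("1", 45.0)
        out = variance_explained(geno, _trait_for(geno, y), [m1])
        assert out[m1] < 0.05

    def test_default_architecture_r2(self, default_panel):
        # defaults target ~10% and ~8% per locus; joint model never explains
        # less than the best single locus (nested OLS guarantee)
        geno, gmap, expr, annot, trait, truth, ppi = default_panel
        m1 = gmap.nearest_marker("1", 45.0)
        m2 = gmap.nearest_marker("2", 45.0)
        out = variance_explained(geno, trait, [m1, m2])
        assert out[m1] == pytest.approx(0.10, abs=0.04)
        assert out[m2] == pytest.approx(0.08, abs=0.04)
        assert out["joint"] >= max(out[m1], out[m2]) - 1e-12
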