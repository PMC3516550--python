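"""IP / TIPC / TIE scoring against brute-force oracles and invariants."""

import numpy as np
import pytest

from tiescore.model import ExpressionMatrix, PpiNetwork, TraitVector
from tiescore.network import CrossGroupNetwork, build_cross_network
from tiescore.scoring import (
    build_records,
    interaction_potential,
    normalize_expression,
    permutation_pvalues,
    rank_table,
    score_network,
    tie_scores,
    tipc,
    TieRecord,
)


def oracle_pearson(x, y):
    """Sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = ((n * sxx - sx**2) * (n * syy - sy**2)) ** 0.5
    return num / den


def oracle_tie(expression, trait, edges, min_degree=5):
    """Fully explicit loops from raw expression to per-gene TIE."""
    genes = expression.genes
    norm = {}
    for g, row in zip(genes, expression.values):
        lo, hi = min(row), max(row)
        norm[g] = [(v - lo) / (hi - lo) for v in row]
    t = list(trait.values)
    edge_tipc = {}
    for a, b in edges:
        ip = [x * y for x, y in zip(norm[a], norm[b])]
        edge_tipc[(a, b)] = oracle_pearson(ip, t) if len(set(ip)) > 1 else 0.0
    out = {}
    for g in genes:
        incident = [e for e in edges if g in e]
        if len(incident) < min_degree:
            out[g] = 0.0
        else:
            out[g] = sum(abs(edge_tipc[e]) for e in incident) / len(incident)
    return out


def _expr(values, mice=None, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    mice = mice or [f"M{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes=genes, mice=mice, values=values)


class TestNormalization:
    def test_endpoints(self):
        norm = normalize_expression(_expr([[0.0, 1.0, 3.0]]))
        np.testing.assert_allclose(norm.values[0], [0.0, 1 / 3, 1.0])

    def test_constant_gene_excluded(self):
        norm = normalize_expression(_expr([[2.0, 2.0, 2.0], [0.0, 1.0, 2.0]]))
        assert norm.excluded == ["g0"]
        assert np.isnan(norm.values[0]).all()


class TestInteractionPotential:
    def test_product_endpoints(self):
        norm = normalize_expression(_expr([[0.0, 2.0, 1.0], [0.0, 4.0, 2.0]]))
        ip = interaction_potential(("g0", "g1"), norm)
        assert ip[1] == 1.0  # both genes at panel max
        assert ip[0] == 0.0  # either gene at panel min

    def test_elementwise_product(self):
        e = np.array([[0.0, 1 / 3, 2 / 3, 1.0]])
        norm = normalize_expression(_expr(np.vstack([e * 3, e * 3])))
        ip = interaction_potential(("g0", "g1"), norm)
        np.testing.assert_allclose(ip, [0.0, 1 / 9, 4 / 9, 1.0])

    def test_alternative_forms(self):
        norm = normalize_expression(_expr([[0.0, 1.0, 0.5], [0.0, 0.5, 1.0]]))
        lo = interaction_potential(("g0", "g1"), norm, form="min")
        geo = interaction_potential(("g0", "g1"), norm, form="geomean")
        np.testing.assert_allclose(lo, [0.0, 0.5, 0.5])
        np.testing.assert_allclose(geo, np.sqrt([0.0, 0.5, 0.5]))


class TestTipc:
    def test_perfect_correlation(self):
        ip = np.array([0.1, 0.4, 0.9, 0.2])
        assert tipc(ip, ip) == pytest.approx(1.0)
        assert tipc(ip, -ip) == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        ip = [0.05, 0.32, 0.77, 0.51, 0.20, 0.98]
        t = [6.4, 3.8, 1.2, 2.5, 9.0, 0.7]
        assert tipc(np.array(ip), np.array(t)) == pytest.approx(
            oracle_pearson(ip, t), abs=1e-12
        )

    def test_constant_ip_flagged_as_zero(self):
        assert tipc(np.full(6, 0.3), np.arange(6.0)) == 0.0


class TestTie:
    def _star(self, n_edges):
        edges = frozenset(("hub", f"n{i}") for i in range(n_edges))
        return CrossGroupNetwork(
            group1=frozenset({"hub"}),
            group2=frozenset(f"n{i}" for i in range(n_edges)),
            edges=edges,
        )

    def test_below_degree_five_is_zero(self):
        net = self._star(4)
        tipcs = {e: 0.9 for e in net.edges}
        assert tie_scores(net, tipcs)["hub"] == 0.0

    def test_mean_absolute_tipc(self):
        net = self._star(5)
        tipcs = dict(zip(sorted(net.edges), [0.2, -0.4, 0.6, -0.8, 1.0]))
        assert tie_scores(net, tipcs)["hub"] == pytest.approx(0.6)

    def test_exponent_option(self):
        net = self._star(5)
        tipcs = {e: 0.5 for e in net.edges}
        assert tie_scores(net, tipcs, exponent=2.0)["hub"] == pytest.approx(0.25)


class TestRankTable:
    def _rec(self, gene, tie, deg, p=1.0, corr=0.0):
        return TieRecord(gene_id=gene, n_interactions=deg, tie=tie,
                         p_value=p, expr_trait_corr=corr)

    def test_degree_breaks_tie(self):
        tab = rank_table([self._rec("b", 0.5, 13), self._rec("a", 0.5, 47)])
        assert list(tab["gene"]) == ["a", "b"]

    def test_all_zero_is_lexicographic(self):
        tab = rank_table([self._rec(g, 0.0, 0) for g in ("c", "a", "b")])
        assert list(tab["gene"]) == ["a", "b", "c"]


class TestPermutations:
    def _setup(self, seed=0, n_mice=40, signal=True):
        rng = np.random.default_rng(seed)
        genes = ["hub"] + [f"n{i}" for i in range(6)] + [f"z{i}" for i in range(3)]
        t = rng.standard_normal(n_mice)
        values = rng.standard_normal((len(genes), n_mice))
        if signal:
            values[0] = -2.0 * t + 0.1 * rng.standard_normal(n_mice)
            for i in range(1, 7):
                values[i] = -1.5 * t + 0.5 * rng.standard_normal(n_mice)
        expr = _expr(values, genes=genes,
                     mice=[f"M{i}" for i in range(n_mice)])
        trait = TraitVector(mice=expr.mice, values=t)
        edges = frozenset(("hub", f"n{i}") for i in range(6))
        net = CrossGroupNetwork(group1=frozenset({"hub"}),
                                group2=frozenset(f"n{i}" for i in range(6)),
                                edges=edges)
        return net, expr, trait

    def test_strong_signal_reaches_minimum_p(self):
        net, expr, trait = self._setup(signal=True)
        ties, pvals = permutation_pvalues(net, expr, trait, n_perm=50, seed=1)
        assert ties["hub"] > 0.5
        assert pvals["hub"] == pytest.approx(1 / 51)

    def test_low_degree_gene_gets_p_one(self):
        net, expr, trait = self._setup(signal=True)
        ties, pvals = permutation_pvalues(net, expr, trait, n_perm=20, seed=1)
        assert all(pvals[f"n{i}"] == 1.0 for i in range(6))  # degree 1 each

    def test_zero_permutations_rejected(self):
        net, expr, trait = self._setup()
        from tiescore.model import ValidationError

        with pytest.raises(ValidationError):
            permutation_pvalues(net, expr, trait, n_perm=0)


def test_full_path_matches_loop_oracle():
    rng = np.random.default_rng(77)
    n_genes, n_mice = 50, 30
    genes = [f"g{i:02d}" for i in range(n_genes)]
    expr = _expr(rng.standard_normal((n_genes, n_mice)), genes=genes,
                 mice=[f"M{i}" for i in range(n_mice)])
    trait = TraitVector(mice=expr.mice, values=rng.standard_normal(n_mice))
    pairs = set()
    while len(pairs) < 120:
        a, b = rng.choice(genes, size=2, replace=False)
        pairs.add(tuple(sorted((a, b))))
    g1, g2 = set(genes[:25]), set(genes[25:])
    net = build_cross_network(PpiNetwork.from_edges(pairs), g1, g2)
    ties, _ = permutation_pvalues(net, expr, trait, n_perm=1, seed=0)
    expected = oracle_tie(expr, trait, sorted(net.edges))
    for g in net.degree:
        assert ties[g] == pytest.approx(expected[g], abs=1e-10)


def test_tie_invariant_under_affine_transforms():
    rng = np.random.default_rng(5)
    net, expr, trait = TestPermutations()._setup(seed=5)
    base, _ = permutation_pvalues(net, expr, trait, n_perm=1, seed=2)
    expr2 = ExpressionMatrix(genes=expr.genes, mice=expr.mice,
                             values=3.5 * expr.values - 12.0)
    trait2 = TraitVector(mice=trait.mice, values=-0.2 * trait.values + 7.0)
    moved, _ = permutation_pvalues(net, expr2, trait2, n_perm=1, seed=2)
    for g in base:
        assert moved[g] == pytest.approx(base[g], abs=1e-10)


def test_score_bounds(default_panel):
    geno, gmap, expr, annot, trait, truth, ppi = default_panel
    net = build_cross_network(
        ppi, truth.group_genes("locus1"), truth.group_genes("locus2")
    )
    tab = score_network(net, expr, trait, n_perm=20, seed=3)
    assert ((tab["tie_score"] >= 0) & (tab["tie_score"] <= 1)).all()
    assert ((tab["p_value"] > 0) & (tab["p_value"] <= 1)).all()
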