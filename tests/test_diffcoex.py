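"""Differential co-expression: formulas, module detection, hubs, KS comparison."""

import numpy as np
import pandas as pd
import pytest

from critix.diffcoex import (
    adjacency_difference,
    compare_focal_networks,
    correlation_matrix,
    detect_modules,
    hub_gene,
    select_beta,
    tom_dissimilarity,
)


def formula_adjacency(case: np.ndarray, control: np.ndarray, beta: int) -> np.ndarray:
    """Straight-from-formula loop evaluator (independent of the vectorised path)."""
    G = case.shape[0]
    d = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            a = np.sign(case[i, j]) * case[i, j] ** 2
            b = np.sign(control[i, j]) * control[i, j] ** 2
            d[i, j] = (0.5 * abs(a - b)) ** beta
    return d


def formula_tom(d: np.ndarray) -> np.ndarray:
    G = d.shape[0]
    t = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            shared = sum(d[i, k] * d[k, j] for k in range(G) if k not in (i, j))
            conn_i = sum(d[i, k] for k in range(G) if k != i)
            conn_j = sum(d[j, k] for k in range(G) if k != j)
            t[i, j] = 1 - (shared + d[i, j]) / (min(conn_i, conn_j) + 1 - d[i, j])
    return t


def random_correlations(rng, G):
    a = rng.uniform(-1, 1, size=(G, G))
    c = (a + a.T) / 2
    np.fill_diagonal(c, 1.0)
    return c


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        x = pd.DataFrame(rng.random((10, 3)), columns=list("abc"))
        c = correlation_matrix(x, "pearson")
        assert np.allclose(np.diag(c), 1.0)

    def test_antimonotone_pair_spearman(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [10.0, 7, 5, 1]})
        c = correlation_matrix(x, "spearman")
        assert c.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        x = pd.DataFrame({"a": [1.0, 4, 2, 3], "b": [2.0, 8, 9, 1]})
        c = correlation_matrix(x, "spearman")
        ra = pd.Series([1.0, 4, 2, 3]).rank()
        rb = pd.Series([2.0, 8, 9, 1]).rank()
        assert c.loc["a", "b"] == pytest.approx(np.corrcoef(ra, rb)[0, 1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2]}), "pearson")

    def test_constant_gene_warns_and_zeroes(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            c = correlation_matrix(x, "pearson")
        assert c.loc["a", "b"] == 0.0 and c.loc["b", "b"] == 1.0


class TestAdjacencyDifference:
    def test_equal_conditions_give_zero(self, rng):
        c = random_correlations(rng, 6)
        assert np.allclose(adjacency_difference(c, c, 3), 0.0)

    def test_known_half_square(self):
        case = np.array([[1.0, 0.8], [0.8, 1.0]])
        control = np.eye(2)
        d = adjacency_difference(case, control, 1)
        assert d[0, 1] == pytest.approx(0.32)

    def test_opposite_perfect_correlations_attain_bound(self):
        case = np.array([[1.0, 1.0], [1.0, 1.0]])
        control = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert adjacency_difference(case, control, 1)[0, 1] == pytest.approx(1.0)

    def test_swap_symmetry_and_formula_oracle(self, rng):
        for _ in range(25):
            G = int(rng.integers(3, 8))
            beta = int(rng.integers(1, 6))
            c1, c2 = random_correlations(rng, G), random_correlations(rng, G)
            d = adjacency_difference(c1, c2, beta)
            np.testing.assert_allclose(d, adjacency_difference(c2, c1, beta), atol=1e-15)
            np.testing.assert_allclose(d, formula_adjacency(c1, c2, beta), atol=1e-12)

    def test_power_relationship(self, rng):
        c1, c2 = random_correlations(rng, 5), random_correlations(rng, 5)
        d1 = adjacency_difference(c1, c2, 1)
        d3 = adjacency_difference(c1, c2, 3)
        np.testing.assert_allclose(d3, d1**3, atol=1e-14)


class TestTomDissimilarity:
    def test_two_gene_network_formula(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        t = tom_dissimilarity(d)
        # empty k-sum: t = 1 - (0 + 0.5)/(min(0.5, 0.5) + 1 - 0.5) = 0.5
        assert t[0, 1] == pytest.approx(0.5)

    def test_empty_adjacency_gives_one_off_diagonal(self):
        t = tom_dissimilarity(np.zeros((4, 4)))
        off = t[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(t), 0.0)

    def test_matches_formula_oracle_on_random_matrices(self, rng):
        for _ in range(25):
            G = int(rng.integers(3, 9))
            a = rng.uniform(0, 1, size=(G, G))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0.0)
            t = tom_dissimilarity(d)
            oracle = formula_tom(d)
            np.fill_diagonal(oracle, 0.0)
            np.testing.assert_allclose(t, oracle, atol=1e-12)
            assert np.allclose(t, t.T)
            assert t.min() >= 0 and t.max() <= 1

    def test_shared_neighbours_reduce_dissimilarity(self):
        # genes 0 and 1 share neighbours 2..4; gene 5 is isolated from them
        G = 6
        d = np.zeros((G, G))
        for k in (2, 3, 4):
            d[0, k] = d[k, 0] = 0.8
            d[1, k] = d[k, 1] = 0.8
        d[0, 1] = d[1, 0] = 0.5
        d[5, 2] = d[2, 5] = 0.1
        t = tom_dissimilarity(d)
        assert t[0, 1] < t[0, 5]


def block_correlations(G, blocks, rho):
    c = np.eye(G)
    for start, size in blocks:
        c[start:start + size, start:start + size] = rho
    np.fill_diagonal(c, 1.0)
    return c


class TestModulesAndBeta:
    def test_two_separated_blocks_found(self):
        case = block_correlations(20, [(0, 10), (10, 10)], 0.9)
        control = np.eye(20)
        d = adjacency_difference(case, control, 1)
        modules = detect_modules(tom_dissimilarity(d), min_module_size=5, cut_height="gap")
        labels = modules.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        assert "grey" not in labels

    def test_planted_three_block_label_agreement(self, rng):
        G = 30
        truth = np.repeat([0, 1, 2], 10)
        d = np.zeros((G, G))
        for i in range(G):
            for j in range(G):
                if i != j and truth[i] == truth[j]:
                    d[i, j] = np.clip(0.7 + 0.05 * rng.standard_normal(), 0, 1)
        d = (d + d.T) / 2
        modules = detect_modules(tom_dissimilarity(d), min_module_size=5, cut_height="gap")
        # agreement up to relabelling: every detected module maps to one block
        frame = pd.DataFrame({"truth": truth, "found": modules.to_numpy()})
        agreement = frame.groupby("found")["truth"].agg(lambda s: s.value_counts().max()).sum()
        assert agreement >= 0.9 * G

    def test_single_value_grid(self):
        case = block_correlations(15, [(0, 8)], 0.9)
        assert select_beta(case, np.eye(15), grid=[6]) == 6

    def test_tie_goes_to_smallest_beta(self):
        # perfectly separated block: every beta finds the same single module
        case = block_correlations(15, [(0, 8)], 0.95)
        beta = select_beta(case, np.eye(15), grid=[5, 6, 7])
        assert beta == 5

    def test_grid_minimiser_matches_exhaustive_recomputation(self):
        rng = np.random.default_rng(5)
        case = block_correlations(24, [(0, 8), (8, 6)], 0.85)
        case += rng.normal(0, 0.03, case.shape)
        case = np.clip((case + case.T) / 2, -1, 1)
        np.fill_diagonal(case, 1.0)
        control = np.eye(24)
        grid = [5, 6, 7, 8]
        chosen = select_beta(case, control, grid=grid)
        keys = {}
        for b in grid:
            mods = detect_modules(tom_dissimilarity(adjacency_difference(case, control, b)),
                                  cut_height="gap")
            sizes = mods[mods != "grey"].value_counts()
            if len(sizes):
                keys[b] = (len(sizes), int(sizes.max()), b)
        assert chosen == min(keys.values())[2]


class TestHubGenes:
    def test_most_connected_gene_wins(self, rng):
        n = 200
        hub_driver = rng.standard_normal(n)
        a = hub_driver + 0.3 * rng.standard_normal(n)
        b = hub_driver + 1.5 * rng.standard_normal(n)
        c = hub_driver + 1.5 * rng.standard_normal(n)
        x = pd.DataFrame({"gA": a, "gB": b, "gC": c})
        modules = pd.Series(["M1"] * 3, index=["gA", "gB", "gC"])
        assert hub_gene(x, modules)["M1"] == "gA"

    def test_two_gene_module_lexicographic_tie(self, rng):
        x = pd.DataFrame({"gB": rng.random(10), "gA": rng.random(10)})
        modules = pd.Series(["M1", "M1"], index=["gB", "gA"])
        # both genes have identical connectivity (one edge each)
        assert hub_gene(x, modules)["M1"] == "gA"

    def test_signed_adjacency_penalises_negative_correlation(self):
        corr_pos, corr_neg = 0.8, -0.8
        adj = lambda c: ((1 + c) / 2) ** 2
        assert adj(corr_pos) > adj(corr_neg)


class TestFocalComparison:
    def test_identical_conditions(self, rng):
        x = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        res = compare_focal_networks(x, x.copy(), "a", list("bcde"))
        assert res.ks_statistic == 0.0 and res.ks_p == 1.0

    def test_fully_separated_correlations(self, rng):
        n = 60
        base = rng.standard_normal(n)
        case = pd.DataFrame({"f": base} | {f"g{i}": base + 0.2 * rng.standard_normal(n) for i in range(6)})
        control = pd.DataFrame({"f": base} | {f"g{i}": -base + 0.2 * rng.standard_normal(n) for i in range(6)})
        res = compare_focal_networks(case, control, "f", [f"g{i}" for i in range(6)])
        assert res.ks_statistic == 1.0

    def test_statistic_matches_ecdf_scan(self, rng):
        x_case = pd.DataFrame(rng.random((30, 11)), columns=["f"] + [f"g{i}" for i in range(10)])
        x_control = pd.DataFrame(rng.random((30, 11)), columns=x_case.columns)
        others = [f"g{i}" for i in range(10)]
        res = compare_focal_networks(x_case, x_control, "f", others)
        a, b = np.sort(res.correlations_case), np.sort(res.correlations_control)
        grid = np.concatenate([a, b])
        ecdf = lambda v, g: np.searchsorted(np.sort(v), g, side="right") / len(v)
        d_brute = np.max(np.abs(ecdf(a, grid) - ecdf(b, grid)))
        assert res.ks_statistic == pytest.approx(d_brute, abs=1e-12)

    def test_focal_in_others_rejected(self, rng):
        x = pd.DataFrame(rng.random((10, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="focal"):
            compare_focal_networks(x, x, "a", ["a", "b"])
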