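"""Statistics layer against closed forms, enumeration oracles and skbio."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from viroscope import (
    anosim,
    bh_adjust,
    bray_curtis,
    group_dissimilarities,
    log_transform,
    pcoa,
    permanova,
    rpkm,
    rpkm_matrix,
    shannon,
    t_volcano,
    wilcoxon_bh,
    zscore_hclust,
)
from viroscope.stats import linkage_to_newick


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(10, 1_000, 1_000_000) == 10.0

    def test_zero_count(self):
        assert rpkm(0, 5_000, 2_000_000) == 0.0

    def test_worked_value(self):
        assert abs(rpkm(57, 4_500, 23_500_000) - 0.539) < 1e-3

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 100)

    def test_linear_in_counts_and_matrix_consistency(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [5, 15]},
                              index=["f1", "f2"])
        lengths = {"f1": 1_000, "f2": 3_000}
        m = rpkm_matrix(counts, lengths, total_mapped=pd.Series({"s1": 1e6, "s2": 1e6}))
        assert m.loc["f1", "s1"] == rpkm(10, 1_000, 1e6)
        m2 = rpkm_matrix(counts * 2, lengths, total_mapped=pd.Series({"s1": 1e6, "s2": 1e6}))
        assert np.allclose(m2.values, 2 * m.values)


class TestBrayCurtis:
    def test_hand_case(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]})
        d = bray_curtis(m)
        assert math.isclose(d.loc["a", "b"], 4 / 12)

    def test_identical_and_disjoint(self):
        m = pd.DataFrame({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 5, 1]})
        d = bray_curtis(m)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_all_zero_samples_warn_distance_zero(self):
        m = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        with pytest.warns(UserWarning):
            d = bray_curtis(m)
        assert d.loc["a", "b"] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.floats(0, 100), min_size=4, max_size=4),
                    min_size=2, max_size=5))
    def test_bounds_symmetry_zero_diagonal(self, rows):
        m = pd.DataFrame(np.array(rows).T, columns=[f"s{i}" for i in range(len(rows))])
        d = bray_curtis(m).values
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


def test_log_transform_exact_powers():
    m = pd.DataFrame({"s": [0.0, 1.0, 7.0]})
    out = log_transform(m)
    assert out["s"].tolist() == [0.0, 1.0, 3.0]


class TestPcoa:
    def test_345_triangle_distances_reproduced(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        coords, evals = pcoa(d)
        for i, j, expect in (("a", "b", 3), ("a", "c", 4), ("b", "c", 5)):
            got = np.linalg.norm(coords.loc[i] - coords.loc[j])
            assert abs(got - expect) < 1e-6

    def test_identical_samples_coincide(self):
        d = pd.DataFrame([[0, 0, 1], [0, 0, 1], [1, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        coords, _ = pcoa(d)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_eigenvalue_sum_equals_gram_trace(self, rng):
        x = rng.random((5, 3))
        from scipy.spatial.distance import cdist

        d = pd.DataFrame(cdist(x, x), index=range(5), columns=range(5))
        _, evals = pcoa(d)
        n = 5
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d.values ** 2) @ j
        assert math.isclose(evals.sum(), np.trace(b), rel_tol=1e-9)

    def test_asymmetric_errors(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            pcoa(d)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.random((6, 4))
        from scipy.spatial.distance import cdist

        ids = [f"s{i}" for i in range(6)]
        d = pd.DataFrame(cdist(x, x), index=ids, columns=ids)
        coords, evals = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, ids))
        np.testing.assert_allclose(
            np.abs(coords.values[:, :3]),
            np.abs(ref.samples.values[:, :3]),
            atol=1e-6,
        )


class TestAnosim:
    def _separated(self):
        ids = list("abcdef")
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d, index=ids, columns=ids)
        design = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(ids)}
        return dm, design

    def test_all_equal_distances_give_r_zero(self):
        ids = list("abcd")
        d = np.ones((4, 4)) - np.eye(4)
        dm = pd.DataFrame(d, index=ids, columns=ids)
        r, _ = anosim(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, n_perm=99, seed=0)
        assert abs(r) < 1e-12

    def test_perfect_separation_exact_enumeration(self):
        dm, design = self._separated()
        r, p = anosim(dm, design, n_perm="exact")
        assert math.isclose(r, 1.0)
        # 20 ordered labelings / 2 symmetric = 10 distinct; only the true one reaches R=1
        assert math.isclose(p, 0.1)

    def test_seeded_permutation_p_matches_exact_within_mc_error(self):
        dm, design = self._separated()
        _, p_exact = anosim(dm, design, n_perm="exact")
        _, p_perm = anosim(dm, design, n_perm=999, seed=5)
        assert abs(p_perm - p_exact) < 3 * math.sqrt(p_exact * (1 - p_exact) / 999) + 2 / 999

    def test_r_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import cdist

        x = rng.random((8, 5))
        ids = [f"s{i}" for i in range(8)]
        d = cdist(x, x)
        dm = pd.DataFrame(d, index=ids, columns=ids)
        design = {s: ("g1" if i < 4 else "g2") for i, s in enumerate(ids)}
        r, _ = anosim(dm, design, n_perm=9, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d, ids), pd.Series(design)[ids].values, permutations=9
        )
        assert math.isclose(r, ref["test statistic"], rel_tol=1e-9)

    def test_singleton_group_errors(self):
        dm, design = self._separated()
        design["a"] = "g3"
        with pytest.raises(ValueError):
            anosim(dm, design, n_perm=9, seed=0)

    def test_permanova_separated_groups(self):
        dm, design = self._separated()
        f, p = permanova(dm, design, n_perm=999, seed=0)
        assert f > 10
        assert p <= 0.11


class TestShannon:
    def test_uniform_four(self):
        assert math.isclose(shannon([1, 1, 1, 1]), math.log(4), rel_tol=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_worked_value(self):
        h = shannon([0.5, 0.25, 0.25])
        assert math.isclose(h, 1.0397, abs_tol=1e-4)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestWilcoxonBh:
    def _design(self):
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        return samples, {s: ("A" if s.startswith("a") else "B") for s in samples}

    def test_extreme_case_exact_enumeration(self):
        samples, design = self._design()
        m = pd.DataFrame([list(range(1, 6)) + list(range(6, 11))],
                         index=["f"], columns=samples, dtype=float)
        (res,) = wilcoxon_bh(m, design, [("A", "B")])
        # oracle: full enumeration of C(10,5)=252 assignments; 2 are as extreme
        assert math.isclose(res.p, 2 / 252, rel_tol=1e-9)
        assert res.direction == "B"

    def test_exact_p_matches_brute_force_enumeration(self):
        samples, design = self._design()
        vals = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 9.3]
        m = pd.DataFrame([vals], index=["f"], columns=samples)
        (res,) = wilcoxon_bh(m, design, [("A", "B")])
        # independent oracle: enumerate all 5-subsets, two-sided rank-sum
        ranks = {v: r for r, v in enumerate(sorted(vals), start=1)}
        obs = sum(ranks[v] for v in vals[:5])
        mu = 5 * 11 / 2
        count = sum(
            abs(sum(ranks[vals[i]] for i in comb) - mu) >= abs(obs - mu) - 1e-9
            for comb in itertools.combinations(range(10), 5)
        )
        assert math.isclose(res.p, count / 252, rel_tol=1e-9)

    def test_identical_groups_p_one(self):
        samples, design = self._design()
        m = pd.DataFrame([[2.0] * 10], index=["f"], columns=samples)
        (res,) = wilcoxon_bh(m, design, [("A", "B")])
        assert res.p == 1.0

    def test_bh_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        q2 = bh_adjust([0.005, 0.04, 0.03, 0.9])
        # step-up by hand: sorted (.005,.03,.04,.9) -> (.02, .06, .0533, .9),
        # monotone enforcement from the top gives (.02, .0533, .0533, .9)
        assert math.isclose(q2[0], 0.02)
        assert math.isclose(q2[3], 0.9)
        assert math.isclose(q2[1], 0.04 * 4 / 3) and math.isclose(q2[2], 0.04 * 4 / 3)

    def test_q_equals_p_for_single_test(self):
        assert bh_adjust([0.2])[0] == 0.2


class TestGroupDissimilarities:
    def _dm(self):
        ids = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        x = rng.random((10, 3))
        from scipy.spatial.distance import cdist

        design = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(ids)}
        return pd.DataFrame(cdist(x, x), index=ids, columns=ids), design

    def test_between_counts(self):
        dm, design = self._dm()
        vals = group_dissimilarities(dm, design, "between", ["g1", "g2"])
        assert len(vals) == 25

    def test_within_counts(self):
        dm, design = self._dm()
        assert len(group_dissimilarities(dm, design, "within", ["g1"])) == 10

    def test_between_and_within_partition_off_diagonal(self):
        dm, design = self._dm()
        b = group_dissimilarities(dm, design, "between", ["g1", "g2"])
        w1 = group_dissimilarities(dm, design, "within", ["g1"])
        w2 = group_dissimilarities(dm, design, "within", ["g2"])
        assert len(b) + len(w1) + len(w2) == 45  # C(10,2)

    def test_unknown_group_errors(self):
        dm, design = self._dm()
        with pytest.raises(KeyError):
            group_dissimilarities(dm, design, "between", ["g1", "nope"])


class TestTVolcano:
    def _data(self, seed=0, fold=None):
        rng = np.random.default_rng(seed)
        samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        design = {s: ("A" if s.startswith("a") else "B") for s in samples}
        x = rng.lognormal(2, 0.5, size=(30, 10))
        if fold:
            x[0, 5:] *= fold
        m = pd.DataFrame(np.log2(x + 1), index=[f"f{i}" for i in range(30)], columns=samples)
        return m, design

    def test_planted_responder_detected(self):
        m, design = self._data(seed=1, fold=8)
        res = t_volcano(m, design, ("A", "B"))
        by_id = {r.feature_id: r for r in res}
        assert by_id["f0"].q < 0.05
        assert by_id["f0"].direction == "B"

    def test_label_swap_negates_effect_keeps_p(self):
        m, design = self._data(seed=2)
        res_ab = t_volcano(m, design, ("A", "B"))
        res_ba = t_volcano(m, design, ("B", "A"))
        for a, b in zip(res_ab, res_ba):
            assert math.isclose(a.p, b.p, rel_tol=1e-9)
            assert math.isclose(a.effect, -b.effect, rel_tol=1e-9)

    def test_degenerate_feature_p_one(self):
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        design = {s: s[0].upper() for s in samples}
        m = pd.DataFrame([[3.0] * 8], index=["f"], columns=samples)
        (res,) = t_volcano(m, design, ("A", "B"))
        assert res.p == 1.0


class TestZscoreHclust:
    def test_rows_normalized(self, rng):
        m = pd.DataFrame(rng.random((6, 8)))
        z, order, _ = zscore_hclust(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_duplicate_rows_merge_first(self, rng):
        base = rng.random(8)
        m = pd.DataFrame([base, base, rng.random(8) * 5, rng.random(8) + 9])
        _, _, link = zscore_hclust(m)
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == 0.0

    def test_constant_row_becomes_zero_with_warning(self, rng):
        m = pd.DataFrame([np.ones(5), rng.random(5)])
        with pytest.warns(UserWarning):
            z, _, _ = zscore_hclust(m)
        assert np.allclose(z.iloc[0], 0)

    def test_three_planted_profiles_recovered_at_k3(self, rng):
        from scipy.cluster.hierarchy import fcluster

        profiles = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
        rows = []
        labels = []
        for k in range(3):
            for _ in range(4):
                rows.append(np.repeat(profiles[k], 5) + rng.normal(0, 0.3, 15))
                labels.append(k)
        m = pd.DataFrame(rows)
        _, _, link = zscore_hclust(m)
        cut = fcluster(link, t=3, criterion="maxclust")
        mapping = {}
        for lab, c in zip(labels, cut):
            mapping.setdefault(lab, set()).add(c)
        assert all(len(s) == 1 for s in mapping.values())
        assert len({next(iter(s)) for s in mapping.values()}) == 3

    def test_newick_round_trip(self, rng):
        from io import StringIO

        from Bio import Phylo

        m = pd.DataFrame(rng.random((4, 6)), index=list("wxyz"))
        _, _, link = zscore_hclust(m)
        nwk = linkage_to_newick(link, list(m.index))
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["w", "x", "y", "z"]
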