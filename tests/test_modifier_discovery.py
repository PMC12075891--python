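import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from hetefx import (
    continuous_cutoff,
    importance_table,
    jitter_cates,
    select_k_beale,
    ward_cluster,
)


class TestJitter:
    def test_deterministic_given_seed(self):
        v = np.linspace(0, 1, 50)
        np.testing.assert_array_equal(jitter_cates(v, 1e-3, seed=5),
                                      jitter_cates(v, 1e-3, seed=5))

    def test_scale_bound(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=1000)
        j = jitter_cates(v, relative_sd=1e-6, seed=1)
        assert np.max(np.abs(j - v)) < 1e-4 * v.std()

    def test_constant_vector_becomes_clusterable(self):
        v = np.full(100, 0.25)
        with pytest.warns(UserWarning, match="constant"):
            j = jitter_cates(v, 1e-3, seed=2)
        assert len(np.unique(j)) == 100

    def test_original_untouched(self):
        v = np.zeros(10) + 1.0
        with pytest.warns(UserWarning):
            jitter_cates(v, 1e-3, seed=0)
        assert np.all(v == 1.0)


class TestSelectK:
    def test_two_separated_modes(self):
        rng = np.random.default_rng(7)
        v = np.r_[rng.normal(-0.2, 0.02, 500), rng.normal(0.1, 0.02, 500)]
        assert select_k_beale(v) == 2

    def test_single_normal_mostly_one_cluster(self):
        hits = sum(
            select_k_beale(np.random.default_rng(s).standard_normal(1000)) == 1
            for s in range(20)
        )
        assert hits >= 16

    def test_three_equal_spikes(self):
        sp = np.r_[np.full(300, -1.0), np.zeros(300), np.full(300, 1.0)]
        assert select_k_beale(jitter_cates(sp, 1e-3, seed=1)) == 3

    def test_guards(self):
        v = np.arange(10.0)
        with pytest.raises(ValueError):
            select_k_beale(v, k_max=1)
        with pytest.raises(ValueError):
            select_k_beale(v, k_max=10)
        with pytest.raises(ValueError):
            select_k_beale(np.zeros(10), k_max=3)

    def test_trace_reports_statistics(self):
        rng = np.random.default_rng(3)
        v = np.r_[rng.normal(-1, 0.05, 200), rng.normal(1, 0.05, 200)]
        k, trace = select_k_beale(v, return_trace=True)
        assert k == 2
        assert {"k", "F", "crit", "significant"} <= set(trace.columns)
        assert bool(trace.loc[trace["k"] == 1, "significant"].iloc[0])


def _greedy_delta_ss(vals, members_a, members_b):
    va, vb = vals[members_a], vals[members_b]
    na, nb = len(va), len(vb)
    return na * nb / (na + nb) * (va.mean() - vb.mean()) ** 2


class TestWardOracle:
    def test_merge_sequence_matches_greedy_minimal_ss_increase(self):
        """Every merge in the Ward tree must be a minimal within-SS-increase
        merge among all current cluster pairs (brute-force oracle, n <= 8)."""
        rng = np.random.default_rng(11)
        for draw in range(50):
            n = int(rng.integers(3, 9))
            vals = rng.normal(size=n)
            Z = linkage(vals.reshape(-1, 1), method="ward")
            clusters = {i: [i] for i in range(n)}
            for step, row in enumerate(Z):
                a, b = int(row[0]), int(row[1])
                actual = _greedy_delta_ss(vals, clusters[a], clusters[b])
                best = min(
                    _greedy_delta_ss(vals, clusters[i], clusters[j])
                    for i in clusters for j in clusters if i < j
                )
                assert actual == pytest.approx(best, rel=1e-10)
                clusters[n + step] = clusters.pop(a) + clusters.pop(b)


class TestWardCluster:
    def test_obvious_geometry(self):
        sol = ward_cluster(np.array([0.0, 0.1, 10.0, 10.1]), 2)
        np.testing.assert_array_equal(sol.labels, [1, 1, 2, 2])
        np.testing.assert_allclose(sol.cluster_cate_means, [0.05, 10.05])
        np.testing.assert_array_equal(sol.cluster_sizes, [2, 2])

    def test_k1_single_cluster(self):
        v = np.array([1.0, 2.0, 3.0])
        sol = ward_cluster(v, 1)
        assert sol.k == 1
        assert sol.cluster_cate_means[0] == pytest.approx(2.0)

    def test_labels_canonical_under_permutation(self):
        rng = np.random.default_rng(5)
        v = np.r_[rng.normal(-1, 0.1, 30), rng.normal(1, 0.1, 30)]
        perm = rng.permutation(len(v))
        sol1 = ward_cluster(v, 2)
        sol2 = ward_cluster(v[perm], 2)
        np.testing.assert_array_equal(sol1.labels[perm], sol2.labels)
        np.testing.assert_allclose(sol1.cluster_cate_means, sol2.cluster_cate_means)

    def test_means_use_unjittered_values(self):
        cate = np.r_[np.full(50, -0.2), np.full(50, 0.1)]
        jit = jitter_cates(cate, 1e-3, seed=0)
        sol = ward_cluster(jit, 2, cate=cate)
        np.testing.assert_allclose(sol.cluster_cate_means, [-0.2, 0.1])

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            ward_cluster(np.arange(4.0), 5)


class TestImportance:
    @staticmethod
    def _solution_with_modifier(m1, m2, n_per=200, seed=0):
        """Two clusters; one modifier engineered to given cluster means."""
        rng = np.random.default_rng(seed)
        cate = np.r_[np.full(n_per, -0.2), np.full(n_per, 0.1)]
        jit = jitter_cates(cate, 1e-3, seed=seed)
        half = np.r_[-np.ones(n_per // 2), np.ones(n_per // 2)]
        # overall SD exactly 10: within-cluster spread a around each mean
        between_var = ((m1 - m2) / 2) ** 2
        a = np.sqrt(100 - between_var)
        mod = np.r_[m1 + a * half, m2 + a * half]
        mods = pd.DataFrame({"egfr": mod})
        sol = ward_cluster(jit, 2, cate=cate, modifiers=mods)
        return sol, mods

    def test_paper_style_arithmetic(self):
        # cluster means 70.74 and 75.31, overall SD 10 -> importance 0.457
        sol, mods = self._solution_with_modifier(70.74, 75.31)
        table = importance_table(sol, mods, threshold=0.2)
        assert table.loc["egfr", "importance"] == pytest.approx(0.457, abs=1e-9)
        assert bool(table.loc["egfr", "selected"])
        assert table.loc["egfr", "cutoff"] == pytest.approx(73.025, abs=1e-9)
        assert round(table.loc["egfr", "cutoff"], 1) == 73.0

    def test_identical_cluster_means_not_selected(self):
        sol, mods = self._solution_with_modifier(73.0, 73.0)
        table = importance_table(sol, mods, threshold=0.2)
        assert table.loc["egfr", "importance"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(table.loc["egfr", "selected"])

    def test_zero_variance_modifier_warns(self):
        sol, _ = self._solution_with_modifier(70.0, 76.0)
        mods = pd.DataFrame({"flat": np.full(400, 3.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            table = importance_table(sol, mods, threshold=0.2)
        assert table.loc["flat", "importance"] == 0.0

    def test_binary_modifier_no_cutoff(self):
        cate = np.r_[np.full(100, -0.2), np.full(100, 0.1)]
        jit = jitter_cates(cate, 1e-3, seed=1)
        mods = pd.DataFrame({"aspirin": np.r_[np.zeros(100), np.ones(100)]})
        sol = ward_cluster(jit, 2, cate=cate, modifiers=mods)
        table = importance_table(sol, mods, threshold=0.2)
        assert bool(table.loc["aspirin", "selected"])
        assert np.isnan(table.loc["aspirin", "cutoff"])
        # perfectly aligned binary modifier: z-diff = 2 (0/1 SD is 0.5)
        assert table.loc["aspirin", "importance"] == pytest.approx(2.0, abs=1e-9)

    def test_jitter_isolation(self):
        """A second jitter seed must not change the selected modifier set in
        a well-separated case (jitter only shapes the tree)."""
        cate = np.r_[np.full(200, -0.2), np.full(200, 0.1)]
        mods = pd.DataFrame({"aspirin": np.r_[np.zeros(200), np.ones(200)]})
        tables = []
        for seed in (0, 99):
            jit = jitter_cates(cate, 1e-3, seed=seed)
            sol = ward_cluster(jit, 2, cate=cate, modifiers=mods)
            tables.append(importance_table(sol, mods, threshold=0.2))
        assert (tables[0]["selected"] == tables[1]["selected"]).all()
        np.testing.assert_allclose(tables[0]["importance"], tables[1]["importance"])


class TestContinuousCutoff:
    @pytest.mark.parametrize("m1,m2,expected_1dp", [
        (75.31, 70.74, 73.0),
        (13.15, 11.96, 12.6),
    ])
    def test_reported_cutoffs(self, m1, m2, expected_1dp):
        assert round(continuous_cutoff(m1, m2), 1) == expected_1dp

    def test_identity(self):
        assert continuous_cutoff(4.2, 4.2) == 4.2

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            continuous_cutoff(np.nan, 1.0)
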