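import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import retrostress as rs
from retrostress.de_stats import anova_oneway_matrix


class TestAnovaOneway:
    def test_two_groups_equal_t_test(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(1, 1, size=7)
            f, p, _ = rs.anova_oneway([a, b])
            t = stats.ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t.statistic**2, rel=1e-10)
            assert p == pytest.approx(t.pvalue, abs=1e-10)

    def test_all_identical_is_degenerate(self):
        f, p, degenerate = rs.anova_oneway([np.ones(3), np.ones(4)])
        assert (f, p, degenerate) == (0.0, 1.0, True)

    def test_matrix_version_matches_scipy(self, design_4groups):
        rng = np.random.default_rng(1)
        samples = design_4groups.sample_ids
        x = pd.DataFrame(
            rng.normal(size=(50, len(samples))),
            index=[f"f{i}" for i in range(50)],
            columns=samples,
        )
        table = anova_oneway_matrix(x, design_4groups)
        groups = [x[s] for s in design_4groups.groups.values()]
        f_ref, p_ref = stats.f_oneway(*[g.to_numpy().T for g in groups], axis=0)
        np.testing.assert_allclose(table["F"], f_ref, rtol=1e-10)
        np.testing.assert_allclose(table["p"], p_ref, rtol=1e-8)

    def test_permutation_oracle(self, design_4groups):
        """Analytic p agrees with a 10 000-shuffle permutation p on null data."""
        rng = np.random.default_rng(2)
        n_feat, n_perm = 200, 10_000
        sizes = [len(s) for s in design_4groups.groups.values()]
        n = sum(sizes)
        x = rng.normal(size=(n_feat, n))
        edges = np.cumsum([0] + sizes)

        def f_stat(mat):
            grand = mat.mean(axis=1, keepdims=True)
            ssb = np.zeros(mat.shape[0])
            ssw = np.zeros(mat.shape[0])
            for lo, hi in zip(edges, edges[1:]):
                g = mat[:, lo:hi]
                m = g.mean(axis=1, keepdims=True)
                ssb += (hi - lo) * (m[:, 0] - grand[:, 0]) ** 2
                ssw += ((g - m) ** 2).sum(axis=1)
            return (ssb / (len(sizes) - 1)) / (ssw / (n - len(sizes)))

        f_obs = f_stat(x)
        exceed = np.zeros(n_feat)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            exceed += f_stat(x[:, perm]) >= f_obs
        p_perm = (exceed + 1) / (n_perm + 1)
        p_analytic = stats.f.sf(f_obs, len(sizes) - 1, n - len(sizes))
        assert np.mean(np.abs(p_analytic - p_perm)) < 0.02


class TestBhAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            rs.bh_adjust([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(rs.bh_adjust([0.3, 0.3, 0.3]), 0.3)
        np.testing.assert_allclose(rs.bh_adjust([0.07]), [0.07])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rs.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            rs.bh_adjust([-0.1])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(rs.bh_adjust(p), ref, rtol=1e-12)

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=30)
    def test_order_equivariance(self, perm):
        p = np.linspace(0.01, 0.9, 8)
        q = rs.bh_adjust(p)
        q_perm = rs.bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestTukeyHsd:
    def test_k2_equals_anova_p(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = rng.normal(size=4), rng.normal(0.5, 1, size=6)
            _, p_anova, _ = rs.anova_oneway([a, b])
            out = rs.tukey_hsd([a, b])
            assert out["p"].iloc[0] == pytest.approx(p_anova, abs=1e-6)

    def test_identical_group_means(self):
        a = np.array([1.0, 2.0, 3.0])
        out = rs.tukey_hsd([a, a + 0.0, a.copy()])
        assert (out["p"] > 0.999).all()

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i * 0.3, 1, size=5) for i in range(3)]
        ours = rs.tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups)
        for row in ours.itertuples():
            i = int(row.group_a[1:])
            j = int(row.group_b[1:])
            assert row.p == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_null_p_values_calibrated(self):
        """Studentized-range p-values are calibrated under the null (k=4
        groups of 3): the Tukey p of each feature's widest pair — the
        family-wise p of the maximum range — is uniform, and every pairwise
        p is stochastically conservative (P(p < 0.05) <= 0.05)."""
        rng = np.random.default_rng(6)
        n_feat = 400
        min_p = np.empty(n_feat)
        any_p = np.empty(n_feat)
        for i in range(n_feat):
            groups = [rng.normal(size=3) for _ in range(4)]
            out = rs.tukey_hsd(groups)
            min_p[i] = out["p"].min()
            any_p[i] = out["p"].iloc[0]
        assert stats.kstest(min_p, "uniform").pvalue > 0.01
        assert (any_p < 0.05).mean() <= 0.05 + 0.02


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,fc,direction",
        [(3.0, 2.0, 2.0, "up"), (2.0, 2.0, 1.0, "down"), (1.415, 2.0, 1.5, "down")],
    )
    def test_examples(self, a, b, fc, direction):
        got_fc, got_dir = rs.fold_change(a, b)
        assert got_fc == pytest.approx(fc, abs=2e-3)
        if fc != 1.0:
            assert got_dir == direction


class TestCallDe:
    def test_planted_recovery(self, de_bench):
        cm, design, truth, norm, de = de_bench
        called = set(de.call_sets["THP1_5_vs_THP1_0"].calls.index)
        planted = set(truth.index[truth["is_de"]])
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(1, len(called))
        assert sensitivity >= 0.8
        assert fdr <= 0.10

    def test_direction_matches_truth_and_delta(self, de_bench):
        cm, design, truth, norm, de = de_bench
        calls = de.call_sets["THP1_5_vs_THP1_0"].calls
        tp = calls.index.intersection(truth.index[truth["is_de"]])
        assert (calls.loc[tp, "direction"] == truth.loc[tp, "direction"]).all()
        assert (
            np.sign(calls["delta"]) == np.where(calls["direction"] == "up", 1, -1)
        ).all()

    def test_threshold_monotonicity(self, de_bench):
        cm, design, truth, norm, de = de_bench
        base = set(de.call_sets["THP1_5_vs_THP1_0"].calls.index)
        stricter_fc = rs.call_de(
            norm.values, design, [("THP1_5", "THP1_0")], fc_min=3.0
        )
        stricter_alpha = rs.call_de(
            norm.values, design, [("THP1_5", "THP1_0")], alpha=0.005
        )
        assert set(stricter_fc.call_sets["THP1_5_vs_THP1_0"].calls.index) <= base
        assert set(stricter_alpha.call_sets["THP1_5_vs_THP1_0"].calls.index) <= base

    def test_null_simulation_call_rate(self):
        cm, design, truth = rs.generate_counts(rs.null_config(), seed=2)
        norm = rs.normalize(cm)
        de = rs.call_de(norm.values, design, [("THP1_5", "THP1_0")])
        assert len(de.call_sets["THP1_5_vs_THP1_0"].calls) / len(norm.values) <= 0.01

    def test_constant_feature_never_called(self, design_4groups):
        samples = design_4groups.sample_ids
        rng = np.random.default_rng(7)
        x = pd.DataFrame(
            rng.normal(5, 1, size=(20, len(samples))),
            index=[f"f{i}" for i in range(20)],
            columns=samples,
        )
        x.loc["f0"] = 4.0
        de = rs.call_de(x, design_4groups, [("THP1_5", "THP1_0")])
        assert "f0" not in de.call_sets["THP1_5_vs_THP1_0"].calls.index
        assert bool(de.table.loc["f0", "degenerate"])

    def test_unknown_group_rejected(self, de_bench):
        cm, design, truth, norm, de = de_bench
        with pytest.raises(ValueError, match="NOPE"):
            rs.call_de(norm.values, design, [("NOPE", "THP1_0")])
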