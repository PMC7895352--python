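import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retrostress as rs
from retrostress.qpcr import PERFECT_SLOPE


def records(cqs, **kw):
    return [
        rs.CqRecord(sample_id="s1", condition="c", target="t", replicate=i + 1, cq=c, **kw)
        for i, c in enumerate(cqs)
    ]


class TestCollapseReplicates:
    def test_triplicate_mean_and_sd(self):
        out = rs.collapse_replicates(records([20.0, 20.2, 20.4]))
        assert out["mean_cq"].iloc[0] == pytest.approx(20.2)
        assert out["sd_cq"].iloc[0] == pytest.approx(0.2)

    def test_single_replicate_flagged(self):
        out = rs.collapse_replicates(records([21.0]))
        assert out["mean_cq"].iloc[0] == 21.0
        assert out["sd_cq"].iloc[0] == 0.0
        assert bool(out["single_replicate"].iloc[0])

    def test_undetermined_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="undetermined"):
            out = rs.collapse_replicates(records([20.0, None, 21.0]))
        assert out["mean_cq"].iloc[0] == pytest.approx(20.5)
        assert out["n_determined"].iloc[0] == 2

    def test_all_undetermined_gives_nan(self):
        with pytest.warns(UserWarning):
            out = rs.collapse_replicates(records([None, None]))
        assert math.isnan(out["mean_cq"].iloc[0])


class TestDdctFold:
    def test_equal_dcts_give_fold_one(self):
        r = rs.ddct_fold(
            {"control": 25.0, "treated": 24.0},
            {"control": 15.0, "treated": 14.0},
            treated="treated", control="control",
        )
        assert r.fold == pytest.approx(1.0)

    def test_ddct_minus_three_gives_eight(self):
        r = rs.ddct_fold(
            {"control": 25.0, "treated": 22.0},
            {"control": 15.0, "treated": 15.0},
            treated="treated", control="control",
        )
        assert r.ddct == pytest.approx(-3.0)
        assert r.fold == pytest.approx(8.0)

    def test_missing_cell_named(self):
        with pytest.raises(ValueError, match="reference.*treated"):
            rs.ddct_fold(
                {"control": 25.0, "treated": 22.0},
                {"control": 15.0, "treated": float("nan")},
                treated="treated", control="control",
            )

    @given(st.floats(-5, 5))
    @settings(deadline=None, max_examples=25)
    def test_machine_offset_invariance(self, c):
        base = rs.ddct_fold(
            {"control": 25.0, "treated": 23.0},
            {"control": 15.0, "treated": 15.5},
            treated="treated", control="control",
        )
        shifted = rs.ddct_fold(
            {"control": 25.0 + c, "treated": 23.0 + c},
            {"control": 15.0 + c, "treated": 15.5 + c},
            treated="treated", control="control",
        )
        assert shifted.fold == pytest.approx(base.fold, rel=1e-12)

    def test_efficiency_corrected_mode(self):
        """At E = 1 the corrected ratio equals 2^(-ΔΔCt); with an imperfect
        target primer the corrected ratio recovers the true fold exactly on
        noiseless data while the plain form is biased."""
        plain = rs.ddct_fold(
            {"control": 25.0, "treated": 22.0},
            {"control": 15.0, "treated": 15.0},
            treated="treated", control="control",
            efficiency_target=1.0, efficiency_reference=1.0,
        )
        assert plain.fold == pytest.approx(8.0)
        e = 0.85
        recs = rs.generate_cq(true_fold=8.0, efficiency=e, noise_sd=0.0)
        means = rs.collapse_replicates(recs)
        t = means[means["target"] == "target"].set_index("condition")["mean_cq"].to_dict()
        r = means[means["target"] == "reference"].set_index("condition")["mean_cq"].to_dict()
        biased = rs.ddct_fold(t, r, treated="treated", control="control")
        corrected = rs.ddct_fold(
            t, r, treated="treated", control="control",
            efficiency_target=e, efficiency_reference=e,
        )
        assert corrected.fold == pytest.approx(8.0, rel=1e-9)
        assert abs(biased.fold - 8.0) > 0.5

    def test_noisy_simulation_recovers_fold(self):
        """Cq noise SD 0.2 with triplicates: estimated fold within
        [6.5, 9.8] of the true 8 in >= 95% of seeded runs."""
        ok = 0
        n = 300
        for seed in range(n):
            recs = rs.generate_cq(true_fold=8.0, noise_sd=0.2, seed=seed)
            means = rs.collapse_replicates(recs)
            t = means[means["target"] == "target"].set_index("condition")["mean_cq"]
            r = means[means["target"] == "reference"].set_index("condition")["mean_cq"]
            fold = rs.ddct_fold(
                t.to_dict(), r.to_dict(), treated="treated", control="control"
            ).fold
            ok += 6.5 <= fold <= 9.8
        assert ok / n >= 0.95


class TestReferenceStability:
    def pairs(self, gene, deltas, base=20.0):
        return pd.DataFrame(
            {
                "gene": gene,
                "pair_id": range(len(deltas)),
                "cq_control": base,
                "cq_exposed": base + np.asarray(deltas),
            }
        )

    def test_identical_cq_ranks_first_with_p_one(self):
        table = pd.concat(
            [self.pairs("ACTB", [0.0] * 6), self.pairs("G6PD", [1.0] * 6)]
        )
        out = rs.reference_stability(table)
        assert out.loc[0, "gene"] == "ACTB"
        assert out.loc[0, "wilcoxon_p"] == 1.0
        assert out.loc[0, "rank"] == 1

    def test_six_same_signed_pairs_exact_p(self):
        table = self.pairs("GAPDH", [0.5, 0.7, 0.6, 0.8, 0.4, 0.9])
        out = rs.reference_stability(table)
        assert out["wilcoxon_p"].iloc[0] == pytest.approx(0.03125)
        assert not out["stable"].iloc[0]

    def test_planted_shift_always_ranks_last(self):
        wins = 0
        n = 500
        for seed in range(n):
            rng = np.random.default_rng(seed)
            table = pd.concat(
                [
                    self.pairs("stable", rng.normal(0, 0.3, 6)),
                    self.pairs("shifted", 2.0 + rng.normal(0, 0.3, 6)),
                ]
            )
            out = rs.reference_stability(table)
            wins += out.loc[0, "gene"] == "stable"
        assert wins / n >= 0.99

    def test_unpaired_rejected(self):
        table = self.pairs("ACTB", [0.1] * 6)
        table.loc[2, "pair_id"] = 0
        with pytest.raises(ValueError):
            rs.reference_stability(table)


class TestEfficiency:
    def test_perfect_slope_is_hundred(self):
        fit = rs.efficiency_from_titration(
            [(a, 30.0 + PERFECT_SLOPE * math.log10(a)) for a in (100, 10, 1, 0.1)]
        )
        assert fit.efficiency_percent == pytest.approx(100.0, abs=1e-9)
        assert fit.passes

    def test_slope_minus_3_6_fails_window(self):
        fit = rs.efficiency_from_titration(
            [(a, 30.0 - 3.6 * math.log10(a)) for a in (100, 10, 1)]
        )
        assert fit.efficiency_percent == pytest.approx(89.6, abs=0.05)
        assert not fit.passes

    def test_twofold_series_recovers_slope(self):
        series = rs.generate_titration(efficiency=1.0)
        fit = rs.efficiency_from_titration(series)
        assert fit.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_amount_rescaling_invariance(self):
        series = rs.generate_titration(efficiency=0.95, noise_sd=0.05, seed=3)
        fit1 = rs.efficiency_from_titration(series)
        fit2 = rs.efficiency_from_titration([(a * 17.0, c) for a, c in series])
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rs.efficiency_from_titration([(10, 20.0), (1, 23.3)])
        with pytest.raises(ValueError, match="2 log10"):
            rs.efficiency_from_titration([(10, 20.0), (5, 21.0), (2.5, 22.0)])


class TestNoRtCheck:
    def test_rules(self):
        assert rs.no_rt_check(22.0, None)
        assert rs.no_rt_check(22.0, float("nan"))
        assert not rs.no_rt_check(22.0, 24.0)       # only 2 cycles later
        assert rs.no_rt_check(22.0, 27.0)           # boundary: exactly margin


class TestBoundInputRatio:
    def test_equal_cq_gives_input_fraction(self):
        assert rs.bound_input_ratio(20.0, 20.0) == pytest.approx(0.1)

    def test_ten_cycles_earlier(self):
        assert rs.bound_input_ratio(10.0, 20.0) == pytest.approx(102.4)

    def test_fraction_scaling(self):
        # a larger measured fraction implies less total RNA, hence a larger
        # percent of input for the same Cq pair
        a = rs.bound_input_ratio(18.0, 20.0, input_fraction=0.001)
        b = rs.bound_input_ratio(18.0, 20.0, input_fraction=0.002)
        assert b == pytest.approx(2 * a)


class TestStrandRatio:
    def test_closed_forms(self):
        assert rs.strand_ratio(20.0, 20.0) == pytest.approx(1.0)
        assert rs.strand_ratio(22.0, 20.0) == pytest.approx(4.0)

    def test_mismatched_amplicon_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rs.strand_ratio(20.0, 20.0, "env", "gag")

    def test_simulated_excess_recovered(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(300):
            cq_anti = 20.0 + rng.normal(0, 0.2)
            cq_sense = 20.0 + math.log2(5.0) + rng.normal(0, 0.2)
            ratios.append(rs.strand_ratio(cq_sense, cq_anti))
        assert 4.0 <= np.median(ratios) <= 6.25


class TestVolcanoTable:
    def table(self, fold, p):
        return pd.DataFrame({"gene": ["g"], "fold": [fold], "p": [p]})

    @pytest.mark.parametrize(
        "fold,p,flag",
        [(4.0, 0.01, True), (4.0, 0.05, False), (1.5, 0.001, False), (2.0, 0.01, False)],
    )
    def test_strict_thresholds(self, fold, p, flag):
        out = rs.volcano_table(self.table(fold, p))
        assert bool(out["significant"].iloc[0]) is flag

    def test_derived_columns_and_validation(self):
        out = rs.volcano_table(self.table(4.0, 0.01))
        assert out["log2_fold"].iloc[0] == pytest.approx(2.0)
        assert out["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            rs.volcano_table(self.table(2.0, 0.0))
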