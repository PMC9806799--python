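"""Gating, percentile filtering, knockdown estimation and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trimscope.analyze import (
    compare_many_to_one,
    estimate_knockdown,
    flag_died,
    gate_positive,
    ratio_features,
    separation_curve,
    top_percentile_filter,
    welch_test,
)


def _table(values, column="ab", condition=None):
    df = pd.DataFrame({column: np.asarray(values, float)})
    df["cell_id"] = np.arange(1, len(df) + 1)
    if condition is not None:
        df["condition"] = condition
    return df


class TestGatePositive:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        null = _table(rng.normal(10, 2, 5000))
        res = gate_positive(null, "ab", null, q=0.99)
        assert res.positive_fraction == pytest.approx(0.01, abs=0.005)

    def test_fully_separated_sample(self):
        null = _table([1, 2, 3, 4, 5])
        treated = _table([10, 11, 12])
        res = gate_positive(treated, "ab", null)
        assert res.positive_fraction == 1.0

    def test_threshold_monotone_in_q(self):
        rng = np.random.default_rng(1)
        null = _table(rng.normal(10, 2, 2000))
        cells = _table(rng.normal(12, 3, 2000))
        thresholds = [gate_positive(cells, "ab", null, q=q).threshold for q in (0.9, 0.95, 0.99)]
        fractions = [gate_positive(cells, "ab", null, q=q).positive_fraction for q in (0.9, 0.95, 0.99)]
        assert thresholds == sorted(thresholds)
        assert fractions == sorted(fractions, reverse=True)

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            gate_positive(_table([]), "ab", _table([1.0]))

    def test_mean_sd_rule(self):
        null = _table([0.0] * 10 + [10.0] * 10)
        res = gate_positive(_table([100.0]), "ab", null, rule="mean_sd", k_sd=2.0)
        expected = 5.0 + 2.0 * np.std(null["ab"], ddof=1)
        assert res.threshold == pytest.approx(expected)


class TestFlagDied:
    def test_robust_threshold_finds_rare_bright_cells(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(1, 0.5, 1000)
        vals[:12] = 80.0
        cells = _table(vals, column="pi")
        out = flag_died(cells, "pi")
        assert out["flag_died"].sum() == 12
        assert out["flag_died"].to_numpy()[:12].all()


class TestTopPercentileFilter:
    def test_full_table_at_100(self):
        df = _table(np.arange(20))
        assert len(top_percentile_filter(df, "ab", 100)) == 20

    def test_top_quarter_of_distinct_values(self):
        df = _table(np.arange(20, dtype=float))
        out = top_percentile_filter(df, "ab", 25)
        assert sorted(out["ab"]) == [15.0, 16.0, 17.0, 18.0, 19.0]

    def test_nestedness(self):
        rng = np.random.default_rng(3)
        df = _table(rng.random(400), condition="targeting")
        subsets = {
            p: set(top_percentile_filter(df, "ab", p)["cell_id"]) for p in (5, 10, 25, 50)
        }
        assert subsets[5] <= subsets[10] <= subsets[25] <= subsets[50]

    def test_within_condition_percentiles(self):
        lo = _table(np.arange(100), condition="NC")
        hi = _table(np.arange(100, 200), condition="targeting")
        df = pd.concat([lo, hi], ignore_index=True)
        out = top_percentile_filter(df, "ab", 10)
        assert (out.groupby("condition").size() == 10).all()

    def test_invalid_percent(self):
        with pytest.raises(ValueError):
            top_percentile_filter(_table([1.0]), "ab", 0)


class TestEstimateKnockdown:
    def test_identical_tables_give_zero(self):
        df = _table(np.random.default_rng(4).random(100) + 1, column="target")
        est = estimate_knockdown(df, df, "target", n_boot=10)
        assert est.fraction == 0.0

    def test_known_reduction(self):
        control = _table(np.full(200, 100.0), column="target")
        treated = _table(np.full(200, 40.0), column="target")
        est = estimate_knockdown(treated, control, "target", n_boot=10)
        assert est.fraction == pytest.approx(0.6)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        control = _table(rng.lognormal(5, 0.5, 500), column="target")
        treated = _table(rng.lognormal(5, 0.5, 500) * 0.4, column="target")
        est = estimate_knockdown(treated, control, "target", n_boot=300, seed=1)
        assert est.ci_low <= est.fraction <= est.ci_high
        assert est.ci_high - est.ci_low < 0.2

    def test_nonpositive_control_mean_rejected(self):
        with pytest.raises(ValueError, match="control mean"):
            estimate_knockdown(
                _table([1.0], column="target"), _table([0.0], column="target"),
                "target", n_boot=5,
            )

    def test_empty_subset_names_mode(self):
        df = _table([1.0, 2.0], column="target")
        empty_pos = pd.Series(False, index=df.index)
        with pytest.raises(ValueError, match="gated"):
            estimate_knockdown(
                df, df, "target", mode="gated",
                positive_treated=empty_pos, positive_control=empty_pos, n_boot=5,
            )

    def test_gated_exceeds_bulk_with_bystanders(self):
        """With non-permeabilized bystander cells diluting the bulk readout,
        gating on delivery-positive cells yields a larger knockdown — the core
        argument for single-cell gating."""
        rng = np.random.default_rng(6)
        n = 4000
        delivered = rng.random(n) < 0.6
        target_t = np.where(delivered, 30.0, 100.0) * rng.lognormal(0, 0.2, n)
        target_c = 100.0 * rng.lognormal(0, 0.2, n)
        ab_t = np.where(delivered, rng.lognormal(5, 0.5, n), 0.0)
        treated = pd.DataFrame({"target": target_t, "ab": ab_t})
        control = pd.DataFrame({"target": target_c, "ab": np.zeros(n)})
        pos_t = pd.Series(delivered, index=treated.index)
        pos_c = pd.Series(True, index=control.index)
        bulk = estimate_knockdown(treated, control, "target", n_boot=10)
        gated = estimate_knockdown(
            treated, control, "target", mode="gated",
            positive_treated=pos_t, positive_control=pos_c, n_boot=10,
        )
        assert gated.fraction > bulk.fraction


class TestRatioFeatures:
    def test_identity_and_constant_ratios(self):
        df = pd.DataFrame({"a": [8.0, 8.0], "b": [2.0, 2.0]})
        out = ratio_features(df, [("a", "a"), ("a", "b")])
        assert (out["ratio_a_a"] == 1.0).all()
        assert (out["ratio_a_b"] == 4.0).all()

    def test_nonpositive_denominator_missing(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 2.0]})
        out = ratio_features(df, [("a", "b")])
        assert np.isnan(out["ratio_a_b"].iloc[0])
        assert out["ratio_a_b_undefined"].iloc[0]

    def test_unknown_channel(self):
        with pytest.raises(KeyError):
            ratio_features(pd.DataFrame({"a": [1.0]}), [("a", "nope")])

    def test_mtor_phospho_tracks_target(self, mtor_run):
        """Degrading the kinase lowers the phospho/total ratio downstream:
        median pAkt/Akt is smaller under targeting than under the control."""
        t = ratio_features(mtor_run["treated"], [("r3_pAkt_mean", "r3_Akt_mean")])
        c = ratio_features(mtor_run["control"], [("r3_pAkt_mean", "r3_Akt_mean")])
        assert (
            t["ratio_r3_pAkt_mean_r3_Akt_mean"].median()
            < c["ratio_r3_pAkt_mean_r3_Akt_mean"].median()
        )


class TestSeparationCurve:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(7)
        df1 = pd.DataFrame({"f": rng.normal(0, 1, 3000), "ab": rng.random(3000)})
        df2 = pd.DataFrame({"f": rng.normal(0, 1, 3000), "ab": rng.random(3000)})
        out = separation_curve(df1, df2, "f", "ab")
        assert (out["effect_size"].dropna() < 0.15).all()

    def test_two_point_hand_computed_smd(self):
        a = pd.DataFrame({"f": [0.0, 2.0] * 20, "ab": np.arange(40, dtype=float)})
        b = pd.DataFrame({"f": [4.0, 6.0] * 20, "ab": np.arange(40, dtype=float)})
        out = separation_curve(a, b, "f", "ab", percentiles=(100, 50))
        var = np.var([0.0, 2.0] * 20, ddof=1)
        expected = 4.0 / np.sqrt(var)  # |1 - 5| / pooled sd (equal variances)
        assert out.loc[0, "effect_size"] == pytest.approx(expected)

    def test_small_subsets_marked_unreliable(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"f": rng.random(100), "ab": rng.random(100)})
        out = separation_curve(df, df, "f", "ab", percentiles=(100, 5), min_n=20)
        assert not out.loc[0, "unreliable"]
        assert out.loc[1, "unreliable"]

    def test_needs_two_levels(self):
        df = pd.DataFrame({"f": [1.0], "ab": [1.0]})
        with pytest.raises(ValueError):
            separation_curve(df, df, "f", "ab", percentiles=(100,))


class TestWelch:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = welch_test(a, a)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        a = np.array([1, 2, 3, 4, 5], float)
        b = np.array([2, 3, 4, 5, 6], float)
        t, df, p = welch_test(a, b)
        se2a, se2b = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_direct = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
        df_direct = (se2a + se2b) ** 2 / (se2a**2 / 4 + se2b**2 / 4)
        p_direct = 2 * stats.t.sf(abs(t_direct), df_direct)
        assert t == pytest.approx(t_direct)
        assert df == pytest.approx(df_direct)
        assert p == pytest.approx(p_direct)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    def test_null_type_i_error_rate(self):
        """Monte-Carlo: at alpha = 0.05 under the null, the Welch rejection
        rate over 10,000 replicates lies in [0.04, 0.06]."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, (10_000, 20))
        b = rng.normal(0, 1, (10_000, 20))
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rate = float((res.pvalue < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_holm_adjustment_hand_example(self):
        rng = np.random.default_rng(10)
        ref = rng.normal(0, 1, 50)
        groups = {
            "null": rng.normal(0, 1, 50),
            "shifted": rng.normal(2, 1, 50),
            "slight": rng.normal(0.5, 1, 50),
        }
        out = compare_many_to_one(groups, ref)
        raw = out.set_index("group")["p"]
        adj = out.set_index("group")["p_holm"]
        order = raw.sort_values().index
        expected = {}
        running = 0.0
        for i, g in enumerate(order):
            running = max(running, (3 - i) * raw[g])
            expected[g] = min(running, 1.0)
        for g in groups:
            assert adj[g] == pytest.approx(expected[g])
        assert (adj >= raw - 1e-12).all()
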