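"""Risk differences, 2x2 tests, (rank-)ANCOVA, Wilcoxon, LRT, MI pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from synotrial.analysis import (
    ComparisonResult,
    PopulationFlags,
    ancova_change,
    binary_test,
    comparisons_to_frame,
    endpoint_table,
    impute_mi,
    interaction_lrt,
    pool_rubin,
    rank_ancova_change,
    risk_difference,
    round_percent,
    safety_table,
    within_group_change,
)


def fisher_oracle(x1, n1, x2, n2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    m = x1 + x2
    rv = hypergeom(n1 + n2, n1, m)
    support = np.arange(max(0, m - n2), min(m, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(x1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestRounding:
    @pytest.mark.parametrize(
        "raw,expected",
        [(58.47, 59), (33.29, 33), (-4.54, -5), (-1.25, -1), (2.67, 3), (0.0, 0)],
    )
    def test_two_stage_half_away(self, raw, expected):
        assert round_percent(raw) == expected


class TestRiskDifference:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,effect,lo,hi",
        [
            (12, 33, 20, 32, 26, 3, 50),
            (17, 38, 23, 41, 11, -11, 33),
            (4, 33, 16, 32, 38, 17, 59),
        ],
    )
    def test_published_poor_stratum_rows(self, x1, n1, x2, n2, effect, lo, hi):
        res = risk_difference(x1, n1, x2, n2)
        assert res.effect_rounded == effect
        assert res.ci_rounded == (lo, hi)

    def test_degenerate_interval_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = risk_difference(0, 10, 0, 10)
        assert res.effect == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_newcombe_option_contains_estimate(self):
        res = risk_difference(4, 33, 16, 32, method="newcombe")
        assert res.ci_low < res.effect < res.ci_high

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            risk_difference(5, 0, 1, 10)
        with pytest.raises(ValueError):
            risk_difference(11, 10, 1, 10)

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for scale in (1, 4, 16):
            res = risk_difference(10 * scale, 40 * scale, 20 * scale, 40 * scale)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=1e-6)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=1e-6)


class TestBinaryTest:
    def test_primary_endpoint_chi_square(self):
        p, method = binary_test(12, 33, 20, 32)
        assert method == "chisq"
        # hand value: 65*(12*12 - 21*20)^2 / (33*32*32*33) = 4.440
        assert p == pytest.approx(0.0351, abs=5e-4)

    def test_identical_proportions_p_one(self):
        p, _ = binary_test(5, 10, 5, 10)
        assert p == pytest.approx(1.0)

    def test_small_expected_cells_trigger_fisher(self):
        p, method = binary_test(1, 5, 4, 5)
        assert method == "fisher"
        assert p == pytest.approx(fisher_oracle(1, 5, 4, 5), abs=1e-12)

    @pytest.mark.parametrize(
        "x1,n1,x2,n2",
        [(1, 5, 4, 5), (2, 8, 7, 9), (0, 6, 3, 7), (1, 12, 9, 11)],
    )
    def test_fisher_matches_exhaustive_enumeration(self, x1, n1, x2, n2):
        p, method = binary_test(x1, n1, x2, n2)
        assert method == "fisher"
        assert p == pytest.approx(fisher_oracle(x1, n1, x2, n2), abs=1e-12)


class TestAncova:
    def test_identical_arms_no_effect(self):
        rng = np.random.default_rng(0)
        b = rng.normal(30, 5, 40)
        f = b - rng.normal(10, 2, 40)
        arm = np.array(["rituximab", "tocilizumab"] * 20)
        res = ancova_change(np.r_[b, b], np.r_[f, f], np.r_[arm, arm[::-1]])
        assert res.effect == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_effect_recovered_exactly(self):
        rng = np.random.default_rng(1)
        b = rng.normal(30, 5, 50)
        arm = np.array(["rituximab"] * 25 + ["tocilizumab"] * 25)
        delta = -3.0
        change = 0.4 * b + np.where(arm == "tocilizumab", delta, 0.0)
        res = ancova_change(b, b + change, arm)
        assert res.effect == pytest.approx(-delta, abs=1e-9)
        assert res.lsmean_ref - res.lsmean_alt == pytest.approx(-delta, abs=1e-9)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(2)
        n = 200
        b = rng.normal(30, 6, 2 * n)
        arm = np.array(["rituximab"] * n + ["tocilizumab"] * n)
        change = -10 + 0.1 * b + np.where(arm == "tocilizumab", -3.0, 0.0)
        change += rng.normal(0, 5, 2 * n)
        res = ancova_change(b, b + change, arm)
        se = 5 * math.sqrt(2 / n)
        assert abs(res.effect - 3.0) <= 3 * se

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            ancova_change([1, 1, 1, 1], [2, 2, 2, 2],
                          ["rituximab", "rituximab", "tocilizumab", "tocilizumab"])


class TestRankAncova:
    def test_monotone_transform_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        b = rng.normal(30, 5, 60)
        f = b - rng.gamma(3, 3, 60)
        arm = np.array(["rituximab", "tocilizumab"] * 30)
        p1 = rank_ancova_change(b, f, arm).p_value
        # strictly increasing transform of the outcome preserves ranks
        p2 = rank_ancova_change(b, b + np.expm1((f - b) / 30), arm).p_value
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_separated_arms_significant(self):
        b = np.linspace(20, 40, 60)
        arm = np.array(["rituximab"] * 30 + ["tocilizumab"] * 30)
        f = b + np.where(arm == "tocilizumab", -20.0, -1.0)
        assert rank_ancova_change(b, f, arm).p_value < 0.001

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        n = 30
        rejections = 0
        reps = 2000
        for _ in range(reps):
            b = rng.normal(30, 5, 2 * n)
            f = b - rng.gamma(2, 4, 2 * n)
            arm = rng.permutation(
                np.array(["rituximab"] * n + ["tocilizumab"] * n)
            )
            if rank_ancova_change(b, f, arm).p_value < 0.05:
                rejections += 1
        assert 0.035 < rejections / reps < 0.065


class TestWilcoxon:
    def test_no_change_p_one(self):
        b = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            assert within_group_change(b, b) == 1.0

    def test_constant_shift_smallest_attainable_p(self):
        b = np.arange(20.0)
        # two-sided exact floor for n=20: 2 * 2^-20
        assert within_group_change(b, b - 5) == pytest.approx(
            2 * 2.0**-20, rel=1e-9
        )

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(5)
        reps, n = 400, 60
        rejections = sum(
            within_group_change(np.zeros(n), rng.normal(0, 1, n)) < 0.05
            for _ in range(reps)
        )
        assert abs(rejections / reps - 0.05) <= 0.035


class TestInteractionLrt:
    @staticmethod
    def simulate(rates, n_per_cell, rng):
        arms, pathos, ys = [], [], []
        for (arm, patho), p in rates.items():
            arms += [arm] * n_per_cell
            pathos += [patho] * n_per_cell
            ys += list(rng.binomial(1, p, n_per_cell))
        return np.array(ys), np.array(arms), np.array(pathos)

    def test_power_at_trial_like_cell_rates(self):
        rates = {
            ("rituximab", "poor"): 0.20,
            ("tocilizumab", "poor"): 0.55,
            ("rituximab", "rich"): 0.50,
            ("tocilizumab", "rich"): 0.48,
        }
        rng = np.random.default_rng(6)
        rejections = sum(
            interaction_lrt(*self.simulate(rates, 1000, rng)) < 0.05
            for _ in range(60)
        )
        assert rejections / 60 > 0.80

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            interaction_lrt([0, 1, 0, 1], ["a"] * 4, ["x", "x", "y", "y"])

    def test_separation_detected(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1] * 4)
        arm = np.where(y == 1, "tocilizumab", "rituximab")
        patho = np.array(["poor", "rich"] * 16)
        with pytest.raises(ValueError, match="separation"):
            interaction_lrt(y, arm, patho)


class TestMultipleImputation:
    def test_no_missing_is_a_no_op(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"baseline": rng.normal(30, 5, 50), "change": rng.normal(-8, 4, 50)}
        )
        completed, pooled = impute_mi(
            df, m=5, seed=1, analysis=lambda d: (d["change"].mean(), 1.0)
        )
        assert all(c.equals(df) for c in completed)
        assert pooled["estimate"] == pytest.approx(df["change"].mean())
        assert pooled["between"] == pytest.approx(0.0)

    def test_mcar_pooled_estimate_near_truth(self):
        rng = np.random.default_rng(8)
        n = 300
        baseline = rng.normal(30, 5, n)
        change = -8 + 0.2 * baseline + rng.normal(0, 3, n)
        df = pd.DataFrame({"baseline": baseline, "change": change})
        truth = df["change"].mean()
        holed = df.copy()
        holed.loc[rng.choice(n, size=60, replace=False), "change"] = np.nan
        _, pooled = impute_mi(
            holed, m=10, seed=2,
            analysis=lambda d: (d["change"].mean(), d["change"].var() / len(d)),
        )
        assert abs(pooled["estimate"] - truth) <= 3 * math.sqrt(pooled["variance"])
        assert pooled["variance"] >= pooled["within"]

    def test_seeded_runs_reproduce(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        df.loc[rng.choice(80, 20, replace=False), "b"] = np.nan
        _, p1 = impute_mi(df, m=4, seed=5, analysis=lambda d: (d["b"].mean(), 1.0))
        _, p2 = impute_mi(df, m=4, seed=5, analysis=lambda d: (d["b"].mean(), 1.0))
        assert p1["estimate"] == p2["estimate"]

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_mi(df, m=2)

    def test_rubin_pooling_arithmetic(self):
        pooled = pool_rubin([1.0, 3.0], [0.5, 0.7])
        assert pooled["estimate"] == pytest.approx(2.0)
        assert pooled["variance"] == pytest.approx(0.6 + 1.5 * 2.0)


class TestEndpointTable:
    def test_per_protocol_nested_in_itt(self, default_trial):
        itt = comparisons_to_frame(endpoint_table(default_trial, "histology", "itt"))
        pp = comparisons_to_frame(
            endpoint_table(default_trial, "histology", "per_protocol")
        )
        merged = itt.merge(pp, on=["endpoint", "stratum"], suffixes=("_itt", "_pp"))
        assert (merged["n_ref_pp"] <= merged["n_ref_itt"]).all()
        assert (merged["n_alt_pp"] <= merged["n_alt_itt"]).all()

    def test_binary_rows_carry_counts_and_method(self, default_trial):
        results = endpoint_table(default_trial, "molecular", "itt")
        binary = [r for r in results if r.x_ref is not None and not r.flagged]
        assert binary, "expected binary endpoint rows"
        for r in binary:
            assert 0 <= r.x_ref <= r.n_ref
            assert r.method in ("chisq", "fisher")

    def test_population_flags_invariants(self):
        with pytest.raises(ValueError):
            PopulationFlags(itt=False, per_protocol=True, safety=False)


class TestSafetyTable:
    def test_published_safety_rows(self):
        # 76/108 vs 94/117 any-AE, 8/108 vs 12/117 SAE
        patients = pd.DataFrame(
            {
                "patient_id": [f"R{i}" for i in range(108)]
                + [f"T{i}" for i in range(117)],
                "as_treated_arm": ["rituximab"] * 108 + ["tocilizumab"] * 117,
            }
        )
        rows = []
        for i in range(76):
            rows.append({"patient_id": f"R{i}", "term": "ae", "serious": False})
        for i in range(94):
            rows.append({"patient_id": f"T{i}", "term": "ae", "serious": False})
        for i in range(8):
            rows.append({"patient_id": f"R{i}", "term": "sae", "serious": True})
        for i in range(12):
            rows.append({"patient_id": f"T{i}", "term": "sae", "serious": True})
        results = safety_table(pd.DataFrame(rows), patients)
        by_name = {r.endpoint: r for r in results}
        ae = by_name["any_adverse_event"]
        sae = by_name["any_serious_adverse_event"]
        assert (ae.effect_rounded, *ae.ci_rounded) == (10, -1, 21)
        assert (sae.effect_rounded, *sae.ci_rounded) == (3, -5, 10)

    def test_recurrent_events_count_once(self):
        patients = pd.DataFrame(
            {"patient_id": ["A", "B"], "as_treated_arm": ["rituximab", "tocilizumab"]}
        )
        events = pd.DataFrame(
            [
                {"patient_id": "A", "term": "infection", "serious": False},
                {"patient_id": "A", "term": "infection", "serious": False},
            ]
        )
        results = safety_table(events, patients)
        ae = [r for r in results if r.endpoint == "any_adverse_event"][0]
        assert ae.x_ref == 1 and ae.x_alt == 0


class TestComparisonResult:
    def test_ci_must_contain_estimate(self):
        with pytest.raises(ValueError):
            ComparisonResult(
                endpoint="e", stratum="s", method="chisq",
                effect=5.0, ci_low=6.0, ci_high=7.0, p_value=0.5,
            )
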