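"""The comparison battery: proportions, routing, factorial tests, post hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from attanest import stats


def factorial_frame(rng, n_per_cell=5, env_shift=0.0, month_shift=0.0):
    rows = []
    for env_i, env in enumerate(("sunny", "shaded")):
        for month in range(1, 5):
            y = rng.normal(
                env_i * env_shift + month * month_shift, 1.0, n_per_cell
            )
            rows.extend(
                {"environment": env, "month": month, "y": v} for v in y
            )
    return pd.DataFrame(rows)


class TestEqualProportions:
    def test_hand_values_91_vs_58(self):
        table = stats.MortalityTable(91, 100, 58, 100)
        plain = stats.equal_proportions_test(table)
        yates = stats.equal_proportions_test(table, continuity_correction=True)
        assert plain.statistic == pytest.approx(28.66, abs=0.01)
        assert yates.statistic == pytest.approx(26.95, abs=0.01)
        assert plain.p_value < 1e-6

    def test_identical_proportions_null(self):
        res = stats.equal_proportions_test(stats.MortalityTable(50, 100, 50, 100))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_symmetric_under_environment_swap(self):
        a = stats.equal_proportions_test(stats.MortalityTable(91, 100, 58, 100))
        b = stats.equal_proportions_test(stats.MortalityTable(58, 100, 91, 100))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_matches_scipy_contingency(self):
        table = stats.MortalityTable(37, 80, 12, 60)
        for correction in (False, True):
            ours = stats.equal_proportions_test(table, correction)
            ref = sps.chi2_contingency(
                [[37, 43], [12, 48]], correction=correction
            )
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            stats.equal_proportions_test(stats.MortalityTable(0, 10, 0, 10))


class TestNormalityGate:
    def test_gaussian_routes_parametric_at_nominal_rate(self, rng):
        routes = [
            stats.normality_gate(rng.normal(size=80))[0] for _ in range(200)
        ]
        rate = np.mean([r == "nonparametric" for r in routes])
        assert rate < 0.12  # false-reject rate near alpha

    def test_exponential_routes_nonparametric(self, rng):
        for _ in range(10):
            route, res = stats.normality_gate(rng.exponential(size=120))
            assert route == "nonparametric"
            assert res.p_value < 0.05

    def test_constant_sample_routes_nonparametric(self):
        route, res = stats.normality_gate([3.0, 3.0, 3.0, 3.0])
        assert route == "nonparametric"
        assert np.isnan(res.statistic)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            stats.normality_gate([1.0, 2.0])


class TestTwoWayAnovaTukey:
    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 300
        for _ in range(reps):
            frame = factorial_frame(rng)
            res = stats.two_way_anova_tukey(frame, "y")
            rejections += res["anova"]["environment"].p_value < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_large_environment_effect_separates_letters(self, rng):
        frame = factorial_frame(rng, env_shift=4.0)
        res = stats.two_way_anova_tukey(frame, "y")
        letters = res["letters"]["environment"]
        assert letters["sunny"] != letters["shaded"]
        assert res["anova"]["environment"].p_value < 1e-6

    def test_null_month_factor_non_significant(self, rng):
        # one month's data duplicated across months: no month effect by design
        base = rng.normal(size=8)
        rows = []
        for env_i, env in enumerate(("sunny", "shaded")):
            for month in range(1, 5):
                for v in base[env_i * 4 : env_i * 4 + 4]:
                    rows.append(
                        {"environment": env, "month": month, "y": v + rng.normal(0, 1e-9)}
                    )
        res = stats.two_way_anova_tukey(pd.DataFrame(rows), "y")
        assert res["anova"]["month"].p_value > 0.5

    def test_empty_cell_raises(self, rng):
        frame = factorial_frame(rng)
        frame = frame[~((frame.environment == "sunny") & (frame.month == 2))]
        with pytest.raises(ValueError, match="cell"):
            stats.two_way_anova_tukey(frame, "y")


class TestScheirerRayHare:
    def test_collapses_to_kruskal_wallis_with_constant_factor(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            sizes = rng.integers(3, 8, size=3)
            y = np.concatenate(
                [rng.integers(0, 10, s).astype(float) for s in sizes]
            )
            g = np.concatenate([[lab] * s for lab, s in zip("xyz", sizes)])
            frame = pd.DataFrame({"y": y, "a": g, "b": "only"})
            srh = stats.scheirer_ray_hare(frame, "y", "a", "b")
            h = srh.loc[srh.term == "a", "H"].iloc[0]
            kw = sps.kruskal(*[y[g == lab] for lab in "xyz"]).statistic
            assert h == pytest.approx(kw, abs=1e-9)

    def test_rank_ss_decomposition_balanced(self, rng):
        frame = factorial_frame(rng, n_per_cell=4)
        srh = stats.scheirer_ray_hare(frame, "y", "environment", "month")
        parts = srh.set_index("term")["ss"]
        lhs = parts[["environment", "month", "interaction", "residual"]].sum()
        assert lhs == pytest.approx(parts["total"], abs=1e-9)

    def test_power_against_environment_shift_only(self, rng):
        frame = factorial_frame(rng, n_per_cell=10, env_shift=2.0)
        srh = stats.scheirer_ray_hare(frame, "y", "environment", "month").set_index("term")
        assert srh.loc["environment", "p_value"] < 1e-4
        assert srh.loc["month", "p_value"] > 0.05

    def test_unbalanced_design_still_decomposes(self, rng):
        frame = factorial_frame(rng, n_per_cell=6, env_shift=1.0).iloc[3:]
        srh = stats.scheirer_ray_hare(frame, "y", "environment", "month")
        assert np.isfinite(srh.loc[srh.term == "environment", "H"]).all()

    def test_all_tied_raises(self):
        frame = pd.DataFrame(
            {"y": 1.0, "a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"]}
        )
        with pytest.raises(ValueError, match="tied"):
            stats.scheirer_ray_hare(frame, "y", "a", "b")


def brute_force_dunn_z(samples: dict) -> dict:
    """Independent oracle: mid-ranks and Dunn z from first principles."""
    pooled = sorted(v for vals in samples.values() for v in vals)
    n = len(pooled)

    def midrank(v):
        below = sum(1 for u in pooled if u < v)
        equal = sum(1 for u in pooled if u == v)
        return below + (equal + 1) / 2.0

    tie_sizes = {}
    for v in pooled:
        tie_sizes[v] = tie_sizes.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_sizes.values())
    var0 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    zs = {}
    labs = sorted(samples)
    for i, g1 in enumerate(labs):
        for g2 in labs[i + 1 :]:
            r1 = sum(midrank(v) for v in samples[g1]) / len(samples[g1])
            r2 = sum(midrank(v) for v in samples[g2]) / len(samples[g2])
            se = (var0 * (1 / len(samples[g1]) + 1 / len(samples[g2]))) ** 0.5
            zs[(g1, g2)] = (r1 - r2) / se
    return zs


class TestDunn:
    def test_identical_groups_z_zero_p_one(self):
        table, letters = stats.dunn_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert table["z"].iloc[0] == 0.0
        assert table["p_adjusted"].iloc[0] == 1.0
        assert letters["a"] == letters["b"]

    def test_matches_hand_rank_oracle_with_ties(self):
        samples = {"a": [1, 2, 2, 5], "b": [2, 3, 6], "c": [6, 7, 8, 9, 5]}
        values = [v for lab in sorted(samples) for v in samples[lab]]
        groups = [lab for lab in sorted(samples) for _ in samples[lab]]
        table, _ = stats.dunn_test(values, groups, p_adjust="none")
        oracle = brute_force_dunn_z(samples)
        for _, row in table.iterrows():
            assert row["z"] == pytest.approx(
                oracle[(row["group1"], row["group2"])], abs=1e-9
            )

    def test_bh_adjustment_is_monotone(self, rng):
        values = rng.normal(size=40) + np.repeat([0, 0.5, 1.0, 3.0], 10)
        groups = np.repeat(list("abcd"), 10)
        table, _ = stats.dunn_test(values, groups)
        ordered = table.sort_values("p_value")
        assert (np.diff(ordered["p_adjusted"]) >= -1e-12).all()
        assert ((table["p_adjusted"] >= table["p_value"] - 1e-12)).all()

    def test_separated_groups_get_distinct_letters(self, rng):
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(8, 1, 15), rng.normal(16, 1, 15)]
        )
        groups = np.repeat(["lo", "mid", "hi"], 15)
        _, letters = stats.dunn_test(values, groups)
        assert len({letters["lo"], letters["mid"], letters["hi"]}) == 3

    def test_validation(self):
        with pytest.raises(ValueError):
            stats.dunn_test([1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            stats.dunn_test([1.0, 2.0], ["a", "b"], p_adjust="bonferroni")


class TestCompactLetterDisplay:
    def test_chain_pattern_shares_middle_letter(self):
        letters = stats.compact_letter_display(
            ["A", "B", "C"], [("A", "C")]
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_all_different(self):
        letters = stats.compact_letter_display(
            ["A", "B", "C"], [("A", "B"), ("A", "C"), ("B", "C")]
        )
        assert len({letters["A"], letters["B"], letters["C"]}) == 3

    def test_no_differences_single_letter(self):
        letters = stats.compact_letter_display(["A", "B", "C"], [])
        assert set(letters.values()) == {"a"}


def test_p_values_always_in_unit_interval(rng):
    frame = factorial_frame(rng, n_per_cell=6, env_shift=1.0, month_shift=0.3)
    srh = stats.scheirer_ray_hare(frame, "y", "environment", "month")
    ps = srh["p_value"].dropna()
    assert ((ps >= 0) & (ps <= 1)).all()
    res = stats.two_way_anova_tukey(frame, "y")
    assert all(0 <= tr.p_value <= 1 for tr in res["anova"].values())
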