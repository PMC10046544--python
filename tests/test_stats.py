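"""Rank tests against enumeration oracles, chi-square/Pearson hand values,
stratification rules and the battery layout."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

import neuroage as na
from neuroage.errors import DegenerateTableError, UndefinedTestError


# --- independent brute-force oracles -------------------------------------


def oracle_signed_rank_p(d):
    """Two-sided exact p by direct enumeration of sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = st.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    tps = [
        np.sum(ranks[np.array(signs, bool)])
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    tps = np.asarray(tps)
    p_le = np.mean(tps <= t_obs + 1e-12)
    p_ge = np.mean(tps >= t_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def oracle_mwu_p(x, y):
    """Two-sided exact p by enumeration of group assignments, with U computed
    by pair counting (a different route than rank sums)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(first_idx):
        a = pooled[list(first_idx)]
        b = np.delete(pooled, list(first_idx))
        return np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :])

    u_obs = u_of(range(n1))
    us = np.asarray([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


# --- Wilcoxon signed-rank --------------------------------------------------


class TestWilcoxon:
    def test_all_positive_small_sample_exact(self):
        res = na.wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2 / 32)
        assert res.statistic == 0.0  # T− = 0

    def test_normal_approximation_closed_form(self):
        res = na.wilcoxon_signed_rank([1, 2, 3, 4, 5], mode="approx")
        assert res.z_value == pytest.approx(-7.5 / np.sqrt(13.75))
        assert res.z_value <= 0  # reported from min(T+, T−)

    def test_antisymmetric_pair_p_is_one(self):
        assert na.wilcoxon_signed_rank([3.0, -3.0]).p_value == 1.0

    def test_zero_differences_dropped(self):
        res = na.wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5])
        assert res.n == 3
        assert "zeros dropped: 2" in res.method_notes

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            na.wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_paired_signature_matches_difference_signature(self):
        x = [5.0, 7.0, 2.0]
        y = [4.0, 9.0, 1.5]
        a = na.wilcoxon_signed_rank(x, y)
        b = na.wilcoxon_signed_rank(np.subtract(x, y))
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            d = rng.normal(size=rng.integers(3, 11))
            ours = na.wilcoxon_signed_rank(d).p_value
            ref = st.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_exact_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(50):
            d = rng.integers(-4, 5, size=rng.integers(2, 9)).astype(float)
            if np.all(d == 0):
                continue
            assert na.wilcoxon_signed_rank(d).p_value == pytest.approx(
                oracle_signed_rank_p(d)
            )

    def test_approximation_close_to_exact_for_small_n(self, rng):
        """For n ≤ 12 the signed-rank normal-approximation p stays within
        0.05 of the enumeration p."""
        gaps = []
        for _ in range(200):
            d = rng.normal(size=12) + rng.choice([0.0, 0.8])
            exact = na.wilcoxon_signed_rank(d, mode="exact").p_value
            approx = na.wilcoxon_signed_rank(d, mode="approx").p_value
            gaps.append(abs(exact - approx))
        assert max(gaps) < 0.05

    def test_pratt_flag_changes_zero_handling(self):
        d = [0.0, 1.0, -2.0, 3.0]
        drop = na.wilcoxon_signed_rank(d, zero_method="drop")
        pratt = na.wilcoxon_signed_rank(d, zero_method="pratt")
        assert "Pratt" in pratt.method_notes
        assert pratt.statistic != drop.statistic


# --- Mann–Whitney U --------------------------------------------------------


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = na.mann_whitney_u([1, 2], [3, 4, 5])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.2)

    def test_identical_multisets_p_one(self):
        assert na.mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(30):
            x = rng.normal(size=rng.integers(2, 7))
            y = rng.normal(size=rng.integers(2, 7))
            ours = na.mann_whitney_u(x, y)
            ref = st.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(40):
            x = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
            y = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
            assert na.mann_whitney_u(x, y).p_value == pytest.approx(oracle_mwu_p(x, y))

    def test_large_sample_z_close_to_exact(self, rng):
        """Without a continuity correction (the convention implied by the
        reported p = 2Φ(z) values) the discrete U distribution at n=6+6 keeps
        the worst-case exact/approx gap just under 0.07; agreement is ~0.05
        on average."""
        diffs = []
        for _ in range(100):
            x = rng.uniform(size=6)
            y = rng.uniform(size=6)
            exact = na.mann_whitney_u(x, y, mode="exact").p_value
            approx = na.mann_whitney_u(x, y, mode="approx").p_value
            diffs.append(abs(exact - approx))
        assert np.mean(diffs) < 0.05
        assert max(diffs) < 0.08

    def test_swapping_groups_flips_z_and_keeps_p(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.7, 1, 12)
        y[:3] = x[:3]  # some ties
        a = na.mann_whitney_u(x, y, mode="approx")
        b = na.mann_whitney_u(y, x, mode="approx")
        assert a.z_value == pytest.approx(-b.z_value)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_sample_undefined(self):
        with pytest.raises(UndefinedTestError):
            na.mann_whitney_u([], [1.0])


# --- chi-square and Pearson ------------------------------------------------


class TestChiSquare:
    def test_hand_value_2x2(self):
        res = na.chi_square([[10, 10], [5, 15]])
        assert res.statistic == pytest.approx(8 / 3)
        assert "df=1" in res.method_notes

    def test_identical_rows_zero(self):
        assert na.chi_square([[7, 13], [7, 13]]).statistic == pytest.approx(0.0)

    def test_hand_value_skewed_table(self):
        assert na.chi_square([[14, 28], [2, 40]]).statistic == pytest.approx(11.1176, abs=1e-3)

    def test_zero_marginal_degenerate(self):
        with pytest.raises(DegenerateTableError):
            na.chi_square([[0, 10], [0, 20]])

    def test_continuity_correction_flag(self):
        plain = na.chi_square([[10, 10], [5, 15]])
        corrected = na.chi_square([[10, 10], [5, 15]], correction=True)
        assert corrected.statistic < plain.statistic


class TestPearson:
    def test_perfect_linear(self):
        res = na.pearson_r([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_value(self):
        res = na.pearson_r([0, 1, 2, 3], [0, 1, 1, 2])
        assert res.statistic == pytest.approx(np.sqrt(9 / 10))

    def test_independent_data_small_r(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert abs(na.pearson_r(x, y).statistic) < 0.1

    def test_zero_variance_degenerate(self):
        with pytest.raises(UndefinedTestError):
            na.pearson_r([1, 1, 1], [1, 2, 3])


# --- stratification and battery -------------------------------------------


def scored_wide(seed=5):
    cfg = na.study_profile(seed=seed)
    cohort, _ = na.generate_cohort(cfg)
    est = na.fit_reference_calibration(cfg.eeg, 300, np.random.default_rng(seed + 1))
    return na.to_wide(na.score_cohort(cohort, est))


class TestStratify:
    def test_sex_partition_sizes(self):
        df = pd.DataFrame({"sex": ["F"] * 5 + ["M"] * 3, "gap_pre": 0.0, "arm": "a"})
        strata = na.stratify(df, "sex")
        assert len(strata["F"]) == 5 and len(strata["M"]) == 3

    def test_zero_gap_goes_to_younger(self):
        df = pd.DataFrame({"gap_pre": [-1.0, 1.0, 0.0], "arm": "a", "sex": "F"})
        strata = na.stratify(df, "baseline_gap_sign")
        assert len(strata["younger"]) == 2 and len(strata["older"]) == 1

    def test_study_profile_older_fraction(self):
        wide = scored_wide()
        strata = na.stratify(wide[wide["arm"] == "nutraceuticals"], "baseline_gap_sign")
        frac = len(strata["older"]) / 42
        assert frac == pytest.approx(15 / 42, abs=0.2)

    def test_unknown_stratifier(self):
        with pytest.raises(ValueError):
            na.stratify(pd.DataFrame(), "height")


class TestBattery:
    def test_every_comparison_appears_once(self):
        frame = na.run_battery(scored_wide()).to_frame()
        keys = list(zip(frame["comparison"], frame["stratum"]))
        assert len(keys) == len(set(keys))
        expected = {
            ("bba_pre_vs_post", "nutraceuticals"),
            ("bba_pre_vs_post", "lifestyle"),
            ("br_pre_vs_post", "nutraceuticals"),
            ("bba_vs_ca_pre", "nutraceuticals"),
            ("bba_vs_ca_post", "lifestyle"),
            ("delta_bba_between_arms", "all"),
            ("delta_gap_between_arms", "all"),
            ("delta_ca_between_arms", "all"),
            ("gap_pre_between_arms", "all"),
            ("gap_post_between_arms", "all"),
            ("delta_bba_between_arms", "sex=F"),
            ("delta_bba_between_arms", "sex=M"),
            ("delta_bba_between_arms", "baseline_gap_sign=older"),
            ("delta_bba_between_arms", "baseline_gap_sign=younger"),
            ("delta_bba_vs_duration", "nutraceuticals"),
            ("delta_bba_vs_duration", "lifestyle"),
            ("symptom_pre_vs_post", "nutraceuticals"),
            ("sex_between_arms", "all"),
        }
        assert expected <= set(keys)

    def test_uncorrected_by_default(self):
        battery = na.run_battery(scored_wide())
        frame = battery.to_frame()
        assert "p_adjusted" not in frame.columns

    def test_optional_correction_flag(self):
        frame = na.run_battery(scored_wide(), correction="bonferroni").to_frame()
        assert "p_adjusted" in frame.columns
        assert (frame["p_adjusted"] >= frame["p_value"] - 1e-12).all()

    def test_incomplete_subject_excluded(self, caplog):
        wide = scored_wide()
        wide.loc[0, "bba_post"] = np.nan
        frame = na.run_battery(wide).to_frame()
        row = frame[(frame["comparison"] == "bba_pre_vs_post")
                    & (frame["stratum"] == wide.loc[0, "arm"])]
        assert int(row["n"].iloc[0]) <= 46  # one subject dropped

    def test_study_profile_effect_is_detected(self):
        """Under the configured rejuvenation effect the within-arm ΔBBA test
        should be clearly significant at n=42."""
        frame = na.run_battery(scored_wide(seed=8)).to_frame()
        row = frame[(frame["comparison"] == "bba_pre_vs_post")
                    & (frame["stratum"] == "nutraceuticals")]
        assert float(row["p_value"].iloc[0]) < 0.05

    def test_group_summary_shape(self):
        summary = na.group_summary(scored_wide())
        assert set(summary["arm"]) == {"nutraceuticals", "lifestyle"}
        assert {"ca_pre_mean", "bba_post_sd", "br_pre_mean", "pct_female"} <= set(summary.columns)
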