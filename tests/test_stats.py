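import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mgsaccade import (
    SimulationParams,
    analyze,
    bin_heuristic_analysis,
    compare_inclusion_rates,
    fisher_z,
    one_sample_t,
    paired_t,
    power_paired_t,
    rm_anova_oneway,
    sensitivity_rerun,
    simulate_scored_cohort,
    summarize,
    tangential_precision,
)
from mgsaccade.stats import condition_matrix


@pytest.fixture(scope="module")
def cohort_table():
    return simulate_scored_cohort(8, 60, SimulationParams(), seed=0)


class TestSummarize:
    def test_matches_groupby_oracle(self, cohort_table):
        """Summary means equal an independent pandas aggregation to 1e-12."""
        s = summarize(cohort_table)
        inc = cohort_table[~cohort_table["excluded"]]
        oracle = inc.groupby(["subject", "condition"])["recall_error_deg"].mean()
        for _, row in s.iterrows():
            assert row["mean_error_deg"] == pytest.approx(
                oracle.loc[(row["subject"], row["condition"])], abs=1e-12
            )
            assert row["n_included"] <= row["n_total"]
            assert 0.0 <= row["prop_included"] <= 1.0

    def test_single_trial_cell(self):
        df = pd.DataFrame({
            "subject": [0], "condition": ["R1"], "recall_error_deg": [2.0],
            "rt_ms": [300.0], "n_saccades": [1], "excluded": [False],
            "final_x": [12.0], "final_y": [0.0], "target_x": [12.0],
            "target_y": [0.0],
        })
        s = summarize(df)
        assert s.iloc[0]["mean_error_deg"] == 2.0
        assert np.isnan(s.iloc[0]["tangential_sd_deg"])  # < 2 trials

    def test_empty_cell_flagged(self, cohort_table):
        df = cohort_table.copy()
        df.loc[(df["subject"] == 0) & (df["condition"] == "R1"), "excluded"] = True
        s = summarize(df)
        cell = s[(s["subject"] == 0) & (s["condition"] == "R1")].iloc[0]
        assert cell["missing"] and np.isnan(cell["mean_error_deg"])
        # listwise drop removes the subject from the matrix
        m = condition_matrix(s, "mean_error_deg")
        assert m.shape[0] == s["subject"].nunique() - 1


def _pingouin_anova(matrix):
    import pingouin as pg

    n, k = matrix.shape
    long = pd.DataFrame({
        "y": matrix.ravel(),
        "subject": np.repeat(np.arange(n), k),
        "cond": np.tile(np.arange(k), n),
    })
    return pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                       detailed=True)


class TestRmAnova:
    def test_against_pingouin_oracle(self):
        """F, dfs, p, and partial eta squared match pingouin on 20 fixtures."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
            res = rm_anova_oneway(m)
            tab = _pingouin_anova(m)
            eff, err = tab.iloc[0], tab.iloc[1]
            assert res.F == pytest.approx(eff["F"], abs=1e-10)
            assert res.df_effect == eff["DF"] and res.df_error == err["DF"]
            assert res.p == pytest.approx(eff["p_unc"], abs=1e-10)
            np2 = eff["SS"] / (eff["SS"] + err["SS"])
            assert res.partial_eta_sq == pytest.approx(np2, abs=1e-10)

    def test_identical_conditions_give_zero_F(self):
        m = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        res = rm_anova_oneway(m)
        assert res.F == 0.0 and res.degenerate

    def test_additive_data_degenerate(self):
        res = rm_anova_oneway(np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]))
        assert res.degenerate and np.isinf(res.F)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan, 3.0], [2.0, 3.0, 4.0]])
        with pytest.raises(ValueError):
            rm_anova_oneway(m)


class TestPairedT:
    def test_equal_vectors(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.dz == 0.0 and res.degenerate

    def test_closed_form_example(self):
        """d = (1, 2, 3): t = 2*sqrt(3), df = 2, dz = 2."""
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2
        assert res.dz == pytest.approx(2.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(5, 40)
            a, b = rng.normal(0, 1, (2, n))
            res = paired_t(a, b)
            d = a - b
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * sps.t.sf(abs(t), n - 1)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)
            assert res.dz == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-10)
            assert np.sign(res.t) == np.sign(res.dz) or res.t == 0


class TestTangentialPrecision:
    def test_on_target_zero(self):
        angles = np.array([0.0, 45.0, 170.0])
        pts = 12.0 * np.c_[np.cos(np.radians(angles)), np.sin(np.radians(angles))]
        assert tangential_precision(pts, angles) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_isometry(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 3, (50, 2)) + [12, 0]
        angles = rng.uniform(0, 360, 50)
        a = -np.radians(angles)
        rot = np.c_[pts[:, 0] * np.cos(a) - pts[:, 1] * np.sin(a),
                    pts[:, 0] * np.sin(a) + pts[:, 1] * np.cos(a)]
        assert np.allclose(np.hypot(*rot.T), np.hypot(*pts.T))

    def test_recovers_generating_sd(self):
        """Pure tangential noise of SD 1.0 deg is recovered within 3%."""
        rng = np.random.default_rng(4)
        n = 10_000
        angles = rng.uniform(0, 360, n)
        noise = rng.normal(0, 1.0, n)
        rad = np.radians(angles)
        pts = np.c_[12 * np.cos(rad) - noise * np.sin(rad),
                    12 * np.sin(rad) + noise * np.cos(rad)]
        sd = tangential_precision(pts, angles)
        assert 0.97 <= sd <= 1.03

    def test_invariant_to_common_rotation(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 360, 200)
        pts = 12.0 * np.c_[np.cos(np.radians(angles)), np.sin(np.radians(angles))]
        pts += rng.normal(0, 0.8, (200, 2))
        base = tangential_precision(pts, angles)
        th = np.radians(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert tangential_precision(pts @ R.T, angles + 37.0) == pytest.approx(
            base, abs=1e-9
        )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(-0.999, 0.999))
def test_fisher_z_antisymmetry(r):
    assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)


def test_fisher_z_caps_unit_correlation():
    assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))
    assert fisher_z(0.0) == 0.0


class TestBinAnalysis:
    def _frame(self, err_by_bin, choice_counts, n_bins=12):
        """Scored table for one subject with bin-resolved errors and choices."""
        centers = 15.0 + 30.0 * np.arange(n_bins)
        rows = []
        for b, e in enumerate(err_by_bin):
            rows.append({"subject": 0, "condition": "R1",
                         "reported_angle_deg": centers[b],
                         "recall_error_deg": e, "excluded": False})
        for b, c in enumerate(choice_counts):
            for _ in range(c):
                rows.append({"subject": 0, "condition": "R2-best",
                             "reported_angle_deg": centers[b],
                             "recall_error_deg": 1.0, "excluded": False})
        return pd.DataFrame(rows)

    def test_perfect_anticorrelation(self):
        """Linear errors against reverse-linear choices give r = -1, finite z."""
        df = self._frame(np.arange(1.0, 13.0), list(range(12, 0, -1)))
        res = bin_heuristic_analysis(df)
        row = res.per_subject.iloc[0]
        assert row["r"] == pytest.approx(-1.0, abs=1e-12)
        assert np.isfinite(row["z"])

    def test_zero_variance_flagged(self):
        df = self._frame(np.full(12, 2.0), [3] * 12)
        res = bin_heuristic_analysis(df)
        assert res.per_subject.iloc[0]["flag"] == "zero_variance"

    def test_too_few_bins_flagged(self):
        df = self._frame([1.0] + [np.nan] * 11, [2, 1] + [0] * 10)
        df = df.dropna()
        res = bin_heuristic_analysis(df)
        assert res.per_subject.iloc[0]["flag"] == "too_few_bins"

    def test_spearman_option(self):
        df = self._frame(np.arange(1.0, 13.0) ** 2, list(range(12, 0, -1)))
        res = bin_heuristic_analysis(df, method="spearman")
        assert res.per_subject.iloc[0]["r"] == pytest.approx(-1.0, abs=1e-12)


class TestInclusionRates:
    def test_identical_rates_give_zero_t(self, cohort_table):
        df = cohort_table.copy()
        df["excluded"] = df.groupby(["subject", "condition"]).cumcount() < 5
        res = compare_inclusion_rates(summarize(df))
        for r in res.values():
            assert r.t == 0.0 and r.degenerate

    def test_constructed_difference_has_right_sign(self, cohort_table):
        df = cohort_table.copy()
        df["excluded"] = False
        # exclude 10% of R1 trials only -> R1 proportion lower
        r1 = df["condition"] == "R1"
        df.loc[r1 & (df.groupby(["subject", "condition"]).cumcount() < 6),
               "excluded"] = True
        res = compare_inclusion_rates(summarize(df))
        assert res["R1_vs_R2-random"].t < 0
        assert res["R1_vs_R2-best"].t < 0
        assert res["R2-random_vs_R2-best"].t == 0.0


class TestPower:
    def test_reference_sample_size(self):
        assert power_paired_t(0.70, 0.80, 0.05) == 19

    def test_monotone_in_effect_size(self):
        assert power_paired_t(0.9) <= power_paired_t(0.7)
        assert power_paired_t(0.5) >= power_paired_t(0.7)

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.power import TTestPower

        for dz in (0.3, 0.5, 0.7, 1.0):
            n = power_paired_t(dz, 0.80, 0.05)
            solver = TTestPower()
            n_sm = int(np.ceil(solver.solve_power(
                effect_size=dz, power=0.80, alpha=0.05, alternative="two-sided"
            )))
            assert n == n_sm

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_paired_t(0.0)
        with pytest.raises(ValueError):
            power_paired_t(0.5, power=1.5)


class TestReports:
    def test_analyze_contains_all_blocks(self, cohort_table):
        report = analyze(cohort_table)
        for key in ("recall_error", "rt", "tangential_sd", "n_saccades",
                    "inclusion", "bin_heuristic"):
            assert key in report
        pw = report["recall_error"]["pairwise"]
        assert set(pw) == {"R1_vs_R2-random", "R1_vs_R2-best",
                           "R2-random_vs_R2-best"}

    def test_sensitivity_noop_when_no_high_excluders(self, cohort_table):
        full = analyze(cohort_table)
        rerun = sensitivity_rerun(cohort_table, exclusion_rate_cutoff=0.99)
        assert rerun["dropped_subjects"] == []
        assert rerun["recall_error"] == full["recall_error"]

    def test_sensitivity_drops_high_excluder(self, cohort_table):
        df = cohort_table.copy()
        m = df["subject"] == 3
        flip = m & (df.groupby(["subject", "condition"]).cumcount() < 33)
        df.loc[flip, "excluded"] = True  # ~55% exclusion for subject 3
        rerun = sensitivity_rerun(df, exclusion_rate_cutoff=0.20)
        assert 3 in rerun["dropped_subjects"]
        assert rerun["n_subjects"] == df["subject"].nunique() - 1
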