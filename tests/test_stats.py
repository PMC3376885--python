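"""Statistical stage: mixed/OLS learning model, chi-square, t-tests, mediation."""

import math

import numpy as np
import pandas as pd
import pytest

from wagertrack.stats import (
    excess_score_test,
    fit_learning_model,
    low_awareness_subset,
    mediation_residuals,
    proportion_histogram,
    recall_regressions,
    uniformity_chisq,
)


def linear_cohort(n_subjects=12, noise_sd=0.0, seed=0):
    """Per-trial table with exact structure RT = 1000 - 250 G - 2 trial."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        G = i / (n_subjects - 1)
        for trial in range(1, 49):
            rt = 1000.0 - 250.0 * G - 2.0 * trial + rng.normal(0, noise_sd)
            rows.append((f"s{i}", G, trial, rt))
    return pd.DataFrame(rows, columns=["participant_id", "G", "trial", "rt_ms"])


class TestLearningModel:
    def test_noiseless_coefficients_recovered(self):
        fit = fit_learning_model(linear_cohort(), response="rt_ms")
        assert fit.terms["G"] == pytest.approx(-250.0, abs=1e-6)
        assert fit.terms["trial"] == pytest.approx(-2.0, abs=1e-6)
        assert fit.terms["G:trial"] == pytest.approx(0.0, abs=1e-6)

    def test_noisy_fit_against_ols_oracle(self):
        # with no subject effects, fixed effects must match plain normal equations
        df = linear_cohort(noise_sd=20.0, seed=3)
        fit = fit_learning_model(df, response="rt_ms")
        X = np.column_stack(
            [np.ones(len(df)), df["G"], df["trial"], df["G"] * df["trial"]]
        )
        beta = np.linalg.lstsq(X, df["rt_ms"], rcond=None)[0]
        assert fit.terms["G"] == pytest.approx(beta[1], abs=2.0)
        assert fit.terms["trial"] == pytest.approx(beta[2], abs=0.1)

    def test_f_stats_have_positive_df_and_valid_p(self):
        fit = fit_learning_model(linear_cohort(noise_sd=10.0, seed=1))
        for F, dfn, dfd, p in fit.f_stats.values():
            assert F >= 0 and dfn > 0 and dfd > 0 and 0 <= p <= 1

    def test_single_subject_rejected(self):
        df = linear_cohort(n_subjects=12)
        with pytest.raises(ValueError):
            fit_learning_model(df[df["participant_id"] == "s0"])


class TestUniformityChisq:
    def test_equal_counts_give_zero(self):
        stat, dof, p = uniformity_chisq([21] * 7)
        assert stat == 0.0 and dof == 6 and p == pytest.approx(1.0)

    def test_all_mass_in_one_bin(self):
        counts = [143, 0, 0, 0, 0, 0, 0]
        stat, dof, _ = uniformity_chisq(counts)
        # direct formula: sum (O-E)^2/E with E = 143/7
        E = 143 / 7
        expected = (143 - E) ** 2 / E + 6 * E
        assert stat == pytest.approx(expected) == pytest.approx(858.0)

    def test_matches_hand_formula_on_random_histograms(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 40, size=7)
            if counts.sum() == 0:
                continue
            stat, _, _ = uniformity_chisq(counts)
            E = counts.sum() / 7
            assert stat == pytest.approx(((counts - E) ** 2 / E).sum())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            uniformity_chisq([0] * 7)

    def test_histogram_lattice_binning(self):
        hist = proportion_histogram([0, 1 / 6, 1 / 6, 1.0])
        assert hist.tolist() == [1, 2, 0, 0, 0, 0, 1]


class TestExcessScoreTest:
    def test_all_zero_scores(self):
        res = excess_score_test([0] * 40)
        assert res["t"] == 0.0 and "zero variance" in res["flags"][0]

    def test_constant_positive_scores_flag_infinite_t(self):
        res = excess_score_test([1] * 40)
        assert math.isinf(res["t"]) and res["t"] > 0

    def test_matches_textbook_formula(self, rng):
        for _ in range(200):
            x = rng.integers(0, 3, size=40) + rng.normal(0, 0.5, 40)
            res = excess_score_test(x)
            m, s = x.mean(), x.std(ddof=1)
            assert res["t"] == pytest.approx(m / (s / math.sqrt(len(x))))
            assert res["df"] == 39


class TestMediation:
    def test_perfectly_explained_outcome(self):
        x = np.linspace(0, 1, 30)
        res = mediation_residuals(x, np.linspace(1, 0, 30), x.copy())
        assert res["r_pred_given_G"] == pytest.approx(0.0, abs=1e-8)

    def test_independent_mediator_matches_partial_correlation(self, rng):
        # y = m + noise with m independent of x: residualizing on x leaves corr(y, m)
        n = 2000
        x = rng.normal(size=n)
        m = rng.normal(size=n)
        y = m + rng.normal(0, 0.5, size=n)
        res = mediation_residuals(x, m, y)
        direct = np.corrcoef(y, m)[0, 1]
        assert res["r_pred_given_G"] == pytest.approx(direct, abs=0.03)
        assert abs(res["r_G_given_pred"]) < 0.1

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            mediation_residuals([1, 2], [1, 2], [1, 2])


class TestRecallRegressions:
    def test_constant_match_is_flagged(self):
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(10)],
                "training_G": np.linspace(0.3, 1.0, 10),
                "recall_G": np.linspace(0.2, 0.9, 10),
                "match_percent": [100.0] * 10,
                "pred_prop_final": np.linspace(0, 1, 10),
                "awareness": np.linspace(100, 400, 10),
                "flagged": [False] * 10,
            }
        )
        out = recall_regressions(df)
        assert any("constant" in f for f in out["flags"])

    def test_simulated_cohort_positive_regularity_link(self, small_tables):
        _, _, scores = small_tables
        out = recall_regressions(scores)
        assert out["r_G_recallG"]["r"] > 0
        assert out["r_G_match"]["r"] > 0


class TestLowAwarenessSubset:
    def test_cutoff_at_floor_is_empty_selection(self, small_tables):
        feats, _, scores = small_tables
        from wagertrack.stats import learning_table

        learning = learning_table(feats, scores)
        with pytest.raises(ValueError, match="empty-selection"):
            low_awareness_subset(learning, scores, cutoff=100.0)

    def test_cutoff_above_ceiling_equals_full_fit(self, small_tables):
        feats, _, scores = small_tables
        from wagertrack.stats import learning_table

        learning = learning_table(feats, scores)
        full = fit_learning_model(learning, response="rt_ms")
        sub = low_awareness_subset(learning, scores, cutoff=400.0)
        assert sub.n_obs == full.n_obs
        assert sub.terms["G"] == pytest.approx(full.terms["G"], rel=1e-6)
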