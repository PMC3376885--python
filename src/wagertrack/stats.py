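"""Statistical analyses over a scored cohort.

The central model is a linear mixed-effects regression of a per-trial
measure (RT, initial distance to next, or initial distance from previous) on
sequence regularity G, trial number, and their interaction, with a
subject-level random intercept:

    y_ij = b0 + b1 * G_i + b2 * Trial_ij + b3 * (G_i x Trial_ij)
           + u_i + e_ij,     u_i ~ N(0, s_u^2)

Per-term F statistics are Wald z^2 with one numerator df; denominator df is
the residual count (n_obs - fixed-effect rank), an approximation flagged in
the output.  If the mixed fit is singular or fails to converge, the model
falls back to OLS with subject-clustered standard errors, also flagged.

Also provided: the chi-square test of block predictive-proportion histograms
against uniformity over the 7 attainable proportions, one-sample t-tests on
block excess scores, the recall/match regressions with G as covariate,
residual-based mediation correlations, and the low-awareness-subset refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Midpoint of the 100-400 awareness scale ("somewhat patterned").
SOMEWHAT_PATTERNED = 250.0

#: The 7 attainable predictive proportions in a 6-trial block.
PROPORTION_LATTICE = np.arange(7) / 6.0


@dataclass
class ModelFit:
    """Fixed-effect estimates and per-term F tests from the learning model."""

    terms: dict[str, float]
    f_stats: dict[str, tuple[float, int, float, float]]  # name -> (F, df_num, df_den, p)
    n_obs: int
    grouping: str
    backend: str  # "mixedlm" or "ols_cluster"
    flags: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.terms[name]


def fit_learning_model(
    table: pd.DataFrame,
    response: str = "rt_ms",
    subject_col: str = "participant_id",
) -> ModelFit:
    """Fit ``response ~ G + trial + G:trial`` with a subject random intercept.

    ``table`` is a long per-trial frame with columns ``response``, ``G``,
    ``trial`` and ``subject_col``; rows with missing response are dropped.
    """
    df = table.dropna(subset=[response, "G", "trial"]).copy()
    subjects = df[subject_col].unique()
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects for the mixed model")
    formula = f"{response} ~ G + trial + G:trial"
    flags: list[str] = []
    backend = "mixedlm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, df, groups=df[subject_col]).fit(reml=True)
        if not fit.converged or not np.isfinite(fit.bse.iloc[:4]).all():
            raise np.linalg.LinAlgError("mixed fit did not converge")
        params = fit.fe_params
        bse = fit.bse[params.index]
    except (np.linalg.LinAlgError, ValueError):
        backend = "ols_cluster"
        flags.append("singular or non-converged mixed fit; subject-clustered OLS fallback")
        ols = smf.ols(formula, df).fit(
            cov_type="cluster", cov_kwds={"groups": df[subject_col]}
        )
        params = ols.params
        bse = ols.bse
    n_obs = len(df)
    df_den = n_obs - len(params)
    terms = {k: float(v) for k, v in params.items()}
    f_stats = {}
    for name in params.index:
        if name == "Intercept":
            continue
        z = params[name] / bse[name]
        F = float(z**2)
        p = float(sps.f.sf(F, 1, df_den))
        f_stats[name] = (F, 1, df_den, p)
    flags.append("denominator df approximated as n_obs - rank")
    return ModelFit(terms=terms, f_stats=f_stats, n_obs=n_obs,
                    grouping=subject_col, backend=backend, flags=flags)


def learning_table(features: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join per-trial features with each participant's sequence G."""
    g = scores.set_index("participant_id")["training_G"]
    out = features.copy()
    out["G"] = out["participant_id"].map(g)
    return out


def uniformity_chisq(counts) -> tuple[float, int, float]:
    """Pearson chi-square of a 7-bin proportion histogram against uniformity.

    ``counts`` are observed counts over the proportions 0, 1/6, ..., 1.
    Returns (statistic, df=6, p).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("invalid-input: zero total count")
    if counts.size != 7:
        raise ValueError("expected 7 bins (proportions 0, 1/6, ..., 1)")
    stat, p = sps.chisquare(counts)
    return float(stat), counts.size - 1, float(p)


def proportion_histogram(props) -> np.ndarray:
    """Bin block proportions onto the 7-point lattice (nearest multiple of 1/6)."""
    props = np.asarray(props, dtype=float)
    idx = np.rint(props * 6).astype(int)
    if (idx < 0).any() or (idx > 6).any():
        raise ValueError("proportions outside [0, 1]")
    return np.bincount(idx, minlength=7)


def excess_score_test(scores) -> dict:
    """One-sample t-test of per-subject block excess scores against zero."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 excess scores")
    flags = []
    if np.allclose(x.std(ddof=1), 0.0):
        if np.allclose(x.mean(), 0.0):
            return {"t": 0.0, "df": x.size - 1, "p": 1.0,
                    "mean": 0.0, "flags": ["zero variance, zero mean"]}
        return {"t": float(np.inf) * np.sign(x.mean()), "df": x.size - 1, "p": 0.0,
                "mean": float(x.mean()), "flags": ["zero variance, nonzero mean"]}
    t, p = sps.ttest_1samp(x, 0.0)
    return {"t": float(t), "df": x.size - 1, "p": float(p),
            "mean": float(x.mean()), "flags": flags}


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def recall_regressions(scores: pd.DataFrame) -> dict:
    """Recall-performance analyses on the scored-cohort table.

    (a) Pearson correlations of training G with recall G and with match
    percent; (b) multiple regression of match percent on final-two-block
    predictive proportion controlling for training G; (c) the same for
    recall G.  Constant columns yield NaN correlations with a flag.
    """
    df = scores[~scores["flagged"]].dropna(
        subset=["training_G", "recall_G", "match_percent", "pred_prop_final"]
    )
    out: dict = {"n": len(df), "flags": []}
    for col, key in (("recall_G", "r_G_recallG"), ("match_percent", "r_G_match")):
        r, p = _pearson(df["training_G"], df[col])
        if np.isnan(r):
            out["flags"].append(f"constant column in {key}")
        out[key] = {"r": r, "p": p}
    for resp, key in (("match_percent", "match_model"), ("recall_G", "recallG_model")):
        if np.allclose(df[resp].std(), 0):
            out[key] = {"flag": "constant response"}
            out["flags"].append(f"constant response in {key}")
            continue
        fit = smf.ols(f"{resp} ~ pred_prop_final + training_G", df).fit()
        out[key] = {
            "coef": {k: float(v) for k, v in fit.params.items()},
            "p": {k: float(v) for k, v in fit.pvalues.items()},
            "r2": float(fit.rsquared),
        }
    return out


def awareness_correlations(scores: pd.DataFrame) -> dict:
    """Pearson correlations of awareness with G, match percent, prediction."""
    df = scores[~scores["flagged"]]
    out = {}
    for col, key in (
        ("training_G", "r_G_awareness"),
        ("match_percent", "r_match_awareness"),
        ("pred_prop_final", "r_pred_awareness"),
    ):
        r, p = _pearson(df[col], df["awareness"])
        out[key] = {"r": r, "p": p}
    return out


def mediation_residuals(x, m, y) -> dict:
    """Residual-based mediation check among G (x), prediction (m), awareness (y).

    Regress y on x and correlate the residuals with m (does prediction
    explain awareness beyond G?); then regress y on m and correlate those
    residuals with x (does G survive partialling out prediction?).
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    res_x = y - sm.OLS(y, sm.add_constant(x)).fit().fittedvalues
    res_m = y - sm.OLS(y, sm.add_constant(m)).fit().fittedvalues
    r_m_given_x, p_m_given_x = _pearson(res_x, m)
    r_x_given_m, p_x_given_m = _pearson(res_m, x)
    if np.allclose(res_x.std(), 0):
        r_m_given_x, p_m_given_x = 0.0, 1.0
    if np.allclose(res_m.std(), 0):
        r_x_given_m, p_x_given_m = 0.0, 1.0
    return {
        "r_pred_given_G": r_m_given_x, "p_pred_given_G": p_m_given_x,
        "r_G_given_pred": r_x_given_m, "p_G_given_pred": p_x_given_m,
    }


def low_awareness_subset(
    learning: pd.DataFrame,
    scores: pd.DataFrame,
    cutoff: float = SOMEWHAT_PATTERNED,
    response: str = "rt_ms",
) -> ModelFit:
    """Refit the learning model on participants with awareness below cutoff.

    Implicit-learning check: even participants reporting low pattern
    awareness should show G-modulated RT facilitation across trials.
    """
    if not 100.0 <= cutoff <= 400.0:
        raise ValueError("cutoff must lie within the 100-400 awareness scale")
    # strict "below cutoff"; the scale ceiling is inclusive (selects everyone,
    # since clipped reports can sit exactly at 400)
    if cutoff >= 400.0:
        mask = scores["awareness"] <= cutoff
    else:
        mask = scores["awareness"] < cutoff
    low = scores.loc[mask, "participant_id"]
    if low.empty:
        raise ValueError("empty-selection: no participants below awareness cutoff")
    sub = learning[learning["participant_id"].isin(set(low))]
    return fit_learning_model(sub, response=response)
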