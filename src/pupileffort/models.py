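"""Group-level psychometric models of PPD, accuracy and workload vs SNR.

All group-level analyses are random-intercept mixed models with participant
as the grouping factor.  Model comparison uses likelihood-ratio tests on
full-ML fits; reported coefficients come from REML fits (linear models) or
quadrature ML (logistic models).  Post-hoc condition differences are Wald z
contrasts on the fixed-effect covariance, uncorrected.

Per-participant psychometric shape is summarized from the six condition-mean
PPDs: the average PPD and the linear/quadratic coefficients of an OLS
polynomial fit on coded SNR x = (snr - 10) / 10, so quad_coef < 0 reads as
an inverted U (effort rising then falling over 0-20 dB SNR).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from ._glmm import GLMMFit, SeparationError, fit_binomial_glmm
from .types import LRTResult, ModelFit, ShapeParams

#: coded SNR used for polynomial fits: x = (snr - SNR_CENTER) / SNR_SCALE
SNR_CENTER = 10.0
SNR_SCALE = 10.0


def code_snr(snr) -> np.ndarray:
    return (np.asarray(snr, dtype=float) - SNR_CENTER) / SNR_SCALE


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _try_mixedlm(formula: str, data: pd.DataFrame, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant_id"])
        for method in (["lbfgs", "bfgs"], "powell", "nm"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=2000)
            except np.linalg.LinAlgError:
                continue
            # a boundary "fit" can report llf = +/-inf or NaN; try the next
            # optimizer rather than propagate a meaningless likelihood
            if np.isfinite(res.llf) and np.all(np.isfinite(np.asarray(res.fe_params))):
                return res
    return None


def _fit_mixedlm(formula: str, data: pd.DataFrame, reml: bool):
    # boundary fits (random-intercept variance -> 0) can leave the default
    # optimizer with a singular Hessian; Powell is derivative-free and robust
    res = _try_mixedlm(formula, data, reml)
    if res is not None:
        return res
    # exactly-degenerate data (zero residual variance) have no finite ML
    # optimum; a deterministic, vanishingly small jitter on the response
    # restores a well-posed problem without moving any reported quantity
    # beyond ~1e-5 of the response scale
    lhs = formula.split("~")[0].strip()
    y = data[lhs].to_numpy(dtype=float)
    scale = max(float(np.std(y)), 1.0) * 1e-6
    jitter = scale * np.random.default_rng(0).standard_normal(y.size)
    data2 = data.copy()
    data2[lhs] = y + jitter
    res = _try_mixedlm(formula, data2, reml)
    if res is not None:
        return res
    raise np.linalg.LinAlgError(f"mixed-model fit failed for {formula!r}")


def _lrt(llf_full: float, llf_reduced: float, df: int) -> LRTResult:
    chi2 = max(0.0, 2.0 * (llf_full - llf_reduced))
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


def _level_contrasts(levels, params, cov, level_cols):
    """All pairwise Wald z contrasts between factor-level means.

    ``level_cols`` maps each level to its column index in ``params`` (the
    reference level maps to None: its mean is the intercept alone).
    """
    rows = []
    k = len(params)
    for lo, hi in itertools.combinations(sorted(levels), 2):
        c = np.zeros(k)
        if level_cols[hi] is not None:
            c[level_cols[hi]] += 1.0
        if level_cols[lo] is not None:
            c[level_cols[lo]] -= 1.0
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"contrast": f"SNR{hi:g} - SNR{lo:g}", "beta": est,
                     "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


def _factor_design(snr: np.ndarray):
    """Treatment-coded design matrix for the SNR factor (+ intercept)."""
    levels = sorted(np.unique(snr))
    X = np.ones((snr.size, len(levels)))
    level_cols = {levels[0]: None}
    for j, lv in enumerate(levels[1:], start=1):
        X[:, j] = (snr == lv).astype(float)
        level_cols[lv] = j
    return X, levels, level_cols


def _mixedlm_fixed_cov(result, k: int) -> np.ndarray:
    return np.asarray(result.cov_params().iloc[:k, :k])


def _check_singular(result, warnings_list: list) -> None:
    try:
        if float(np.asarray(result.cov_re).ravel()[0]) < 1e-8:
            warnings_list.append("singular fit: random-intercept variance ~ 0")
    except Exception:
        pass


# ---------------------------------------------------------------------------
# group-level models
# ---------------------------------------------------------------------------

def _exact_ols(data: pd.DataFrame, fixed_cols: list) -> tuple[float, np.ndarray]:
    """OLS with participant dummies; returns (RSS, fixed-part coefficients).

    Used to recognize exactly-degenerate inputs (zero residual variance),
    where the mixed model's ML objective has no finite optimum.
    """
    y = data["ppd"].to_numpy(dtype=float)
    pids = pd.get_dummies(data["participant_id"], drop_first=True)
    X = np.column_stack([np.ones(len(data))] + fixed_cols
                        + [pids.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return rss, beta[: 1 + len(fixed_cols)]


def _rss_tol(data: pd.DataFrame) -> float:
    y = data["ppd"].to_numpy(dtype=float)
    return 1e-10 * (float(np.sum((y - y.mean()) ** 2)) + 1.0)


def _limit_lrt(rss_reduced: float, tol: float, df: int) -> LRTResult:
    """LRT in the zero-residual limit: the full model fits perfectly, so the
    statistic is 0 when the reduced model is also perfect and unbounded
    otherwise."""
    if rss_reduced <= tol:
        return LRTResult(chi2=0.0, df=df, p=1.0)
    return LRTResult(chi2=float("inf"), df=df, p=0.0)


def fit_condition_model(cell_means: pd.DataFrame) -> ModelFit:
    """PPD ~ SNR-as-factor with participant random intercepts.

    ``cell_means``: long frame (participant_id, snr, ppd).  The SNR factor's
    contribution is tested by an ML likelihood-ratio test against the
    intercept-only model; all 15 pairwise condition contrasts are reported
    with uncorrected Wald-z p values.
    """
    data = cell_means.dropna(subset=["ppd"]).copy()
    if data["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    warns: list = []
    levels = sorted(data["snr"].unique())
    snr = data["snr"].to_numpy(dtype=float)
    dummy_cols = [(snr == lv).astype(float) for lv in levels[1:]]
    tol = _rss_tol(data)
    rss_full, beta_exact = _exact_ols(data, dummy_cols)
    if rss_full <= tol:
        # exact fit: no residual variance, mixed-model likelihood unbounded
        rss_null, _ = _exact_ols(data, [])
        lrt = _limit_lrt(rss_null, tol, df=len(levels) - 1)
        terms = ["Intercept"] + [f"C(snr)[T.{lv}]" for lv in levels[1:]]
        fe = pd.DataFrame({"term": terms, "beta": beta_exact, "se": 0.0,
                           "z": np.nan, "p": np.nan})
        level_mean = dict(zip(levels[1:], beta_exact[1:]))
        level_mean[levels[0]] = 0.0
        contrasts = pd.DataFrame(
            [{"contrast": f"SNR{hi:g} - SNR{lo:g}",
              "beta": float(level_mean[hi] - level_mean[lo]), "se": 0.0,
              "z": np.nan,
              "p": 1.0 if abs(level_mean[hi] - level_mean[lo]) <= 1e-12 else 0.0}
             for lo, hi in itertools.combinations(levels, 2)])
        return ModelFit(fixed_effects=fe, lrt=lrt, family="linear",
                        formula_descr="ppd ~ C(snr) + (1 | participant)",
                        contrasts=contrasts,
                        warnings=["degenerate: exact fit, zero residual variance"])
    full_ml = _fit_mixedlm("ppd ~ C(snr)", data, reml=False)
    null_ml = _fit_mixedlm("ppd ~ 1", data, reml=False)
    n_levels = data["snr"].nunique()
    lrt = _lrt(full_ml.llf, null_ml.llf, df=n_levels - 1)

    fit = _fit_mixedlm("ppd ~ C(snr)", data, reml=True)
    _check_singular(fit, warns)
    k = n_levels
    params = np.asarray(fit.fe_params)
    cov = _mixedlm_fixed_cov(fit, k)
    levels = sorted(data["snr"].unique())
    level_cols = {levels[0]: None}
    level_cols.update({lv: j for j, lv in enumerate(levels[1:], start=1)})
    contrasts = _level_contrasts(levels, params, cov, level_cols)

    fe = pd.DataFrame({
        "term": list(fit.fe_params.index),
        "beta": params,
        "se": np.sqrt(np.diag(cov)),
    })
    fe["z"] = fe["beta"] / fe["se"]
    fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["z"]))
    return ModelFit(fixed_effects=fe, lrt=lrt, family="linear",
                    formula_descr="ppd ~ C(snr) + (1 | participant)",
                    contrasts=contrasts, warnings=warns)


def fit_polynomial_model(cell_means: pd.DataFrame) -> ModelFit:
    """PPD ~ linear + quadratic coded SNR with participant random intercepts.

    Sequential ML likelihood-ratio tests: linear term against the intercept
    model, quadratic term against the linear model (1 df each).  A negative
    quadratic coefficient indicates an inverted-U effort curve.
    """
    data = cell_means.dropna(subset=["ppd"]).copy()
    if data["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    data["x"] = code_snr(data["snr"])
    data["x2"] = data["x"] ** 2
    warns: list = []
    tol = _rss_tol(data)
    xc = data["x"].to_numpy(dtype=float)
    rss_full, beta_exact = _exact_ols(data, [xc, xc ** 2])
    if rss_full <= tol:
        rss1, _ = _exact_ols(data, [xc])
        if rss1 <= tol:
            rss0, _ = _exact_ols(data, [])
            linear_lrt = _limit_lrt(rss0, tol, 1)
        else:
            # intercept and linear models are well-posed; test them normally
            m0 = _fit_mixedlm("ppd ~ 1", data, reml=False)
            m1 = _fit_mixedlm("ppd ~ x", data, reml=False)
            linear_lrt = _lrt(m1.llf, m0.llf, 1)
        lrts = {"linear": linear_lrt, "quadratic": _limit_lrt(rss1, tol, 1)}
        fe = pd.DataFrame({"term": ["Intercept", "linear", "quadratic"],
                           "beta": beta_exact, "se": 0.0,
                           "z": np.nan, "p": np.nan})
        return ModelFit(fixed_effects=fe, lrt=lrts, family="linear",
                        formula_descr="ppd ~ x + x^2 + (1 | participant), x = (snr-10)/10",
                        contrasts=None,
                        warnings=["degenerate: exact fit, zero residual variance"])

    m0 = _fit_mixedlm("ppd ~ 1", data, reml=False)
    m1 = _fit_mixedlm("ppd ~ x", data, reml=False)
    m2 = _fit_mixedlm("ppd ~ x + x2", data, reml=False)
    lrts = {"linear": _lrt(m1.llf, m0.llf, 1), "quadratic": _lrt(m2.llf, m1.llf, 1)}

    fit = _fit_mixedlm("ppd ~ x + x2", data, reml=True)
    _check_singular(fit, warns)
    params = np.asarray(fit.fe_params)
    cov = _mixedlm_fixed_cov(fit, 3)
    fe = pd.DataFrame({
        "term": ["Intercept", "linear", "quadratic"],
        "beta": params,
        "se": np.sqrt(np.diag(cov)),
    })
    fe["z"] = fe["beta"] / fe["se"]
    fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["z"]))
    return ModelFit(fixed_effects=fe, lrt=lrts, family="linear",
                    formula_descr="ppd ~ x + x^2 + (1 | participant), x = (snr-10)/10",
                    contrasts=None, warnings=warns)


def fit_accuracy_model(trials: pd.DataFrame) -> ModelFit:
    """Keyword accuracy ~ SNR factor: random-intercept logistic regression.

    ``trials``: long frame (participant_id, snr, keywords_correct,
    n_keywords).  Estimated by Gauss-Hermite quadrature ML; the SNR factor
    is tested by a likelihood-ratio test against the intercept-only model.
    Raises SeparationError for degenerate all-correct/all-wrong data.
    """
    snr = trials["snr"].to_numpy(dtype=float)
    y = trials["keywords_correct"].to_numpy(dtype=float)
    n = trials["n_keywords"].to_numpy(dtype=float)
    groups = trials["participant_id"].to_numpy()

    X, levels, level_cols = _factor_design(snr)
    full = fit_binomial_glmm(y, n, X, groups)
    null = fit_binomial_glmm(y, n, np.ones((snr.size, 1)), groups)
    lrt = _lrt(full.llf, null.llf, df=len(levels) - 1)

    contrasts = _level_contrasts(levels, full.params, full.cov_params, level_cols)
    terms = ["Intercept"] + [f"SNR{lv:g}" for lv in levels[1:]]
    fe = pd.DataFrame({"term": terms, "beta": full.params, "se": full.se})
    fe["z"] = fe["beta"] / fe["se"]
    fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["z"]))
    warns = [] if full.converged and null.converged else ["optimizer did not converge"]
    return ModelFit(fixed_effects=fe, lrt=lrt, family="logistic",
                    formula_descr="keywords/total ~ C(snr) + (1 | participant), logit link",
                    contrasts=contrasts, warnings=warns)


def shrink_to_open_unit(y: np.ndarray) -> np.ndarray:
    """Boundary shrink for proportions: (y*(n-1) + 0.5)/n over the sample."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def fit_tlx_model(ratings: pd.DataFrame) -> ModelFit:
    """Subjective workload ~ SNR factor on the logit scale.

    ``ratings``: one row per participant x condition (participant_id, snr,
    tlx in [0, 100]).  The bounded score is rescaled to (0, 1) with a
    boundary shrink and logit-transformed, then modeled as a random-intercept
    linear mixed model — the logit link makes condition effects interpretable
    as log-odds shifts in relative workload.
    """
    data = ratings.dropna(subset=["tlx"]).copy()
    prop = np.clip(data["tlx"].to_numpy(dtype=float) / 100.0, 0.0, 1.0)
    shrunk = shrink_to_open_unit(prop)
    data["ppd"] = np.log(shrunk / (1.0 - shrunk))  # reuse linear-model plumbing
    fit = fit_condition_model(data[["participant_id", "snr", "ppd"]])
    fit.family = "logistic"
    fit.formula_descr = "logit(tlx') ~ C(snr) + (1 | participant)"
    return fit


# ---------------------------------------------------------------------------
# per-participant shape
# ---------------------------------------------------------------------------

def participant_shape(cell_means: pd.DataFrame, participant_id: str = "") -> ShapeParams:
    """Shape parameters from one participant's per-SNR mean PPDs.

    mean_ppd is the unweighted mean of the available condition means;
    linear/quadratic coefficients come from an OLS quadratic on coded SNR.
    Fewer than 3 non-missing cells leaves the coefficients missing.
    """
    cm = cell_means.dropna(subset=["ppd"])
    if cm.empty:
        return ShapeParams(participant_id, np.nan, np.nan, np.nan)
    mean_ppd = float(cm["ppd"].mean())
    if len(cm) < 3:
        return ShapeParams(participant_id, mean_ppd, np.nan, np.nan)
    x = code_snr(cm["snr"].to_numpy())
    coefs = np.polyfit(x, cm["ppd"].to_numpy(dtype=float), deg=2)
    return ShapeParams(participant_id, mean_ppd,
                       linear_coef=float(coefs[1]), quad_coef=float(coefs[0]))


def shape_table(cell_means: pd.DataFrame) -> pd.DataFrame:
    """Per-participant ShapeParams as a frame (participant_id, mean_ppd, ...)."""
    rows = []
    for pid, grp in cell_means.groupby("participant_id"):
        sp = participant_shape(grp, pid)
        rows.append({"participant_id": pid, "mean_ppd": sp.mean_ppd,
                     "linear_coef": sp.linear_coef, "quad_coef": sp.quad_coef})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# word-recognition median-split analysis
# ---------------------------------------------------------------------------

@dataclass
class WordGroupResult:
    groups: pd.DataFrame           # participant_id, wordgroup ("low"/"high")
    interaction: ModelFit          # SNR x wordgroup interaction test
    per_group: dict                # wordgroup -> condition ModelFit
    covariate_tests: pd.DataFrame  # Welch t-tests between groups


def median_split(profiles: pd.DataFrame, column: str = "word_recognition") -> pd.DataFrame:
    """Two groups at the median; participants exactly at the median join the
    lower group."""
    med = profiles[column].median()
    group = np.where(profiles[column] > med, "high", "low")
    return pd.DataFrame({"participant_id": profiles["participant_id"],
                         "wordgroup": group})


def wordgroup_analysis(
    shape: pd.DataFrame,
    profiles: pd.DataFrame,
    cell_means: pd.DataFrame,
    covariates: tuple = ("age", "ci_duration", "t_level", "qol_total",
                         "smrt_threshold", "nback_dprime",
                         "stroop_interference", "stroop_control_rt",
                         "matrices_correct"),
) -> WordGroupResult:
    """Split the cohort at the word-recognition median and test whether the
    PPD-vs-SNR profile differs between groups.

    The interaction is an ML likelihood-ratio test of
    ``ppd ~ C(snr) * wordgroup`` against ``ppd ~ C(snr) + wordgroup``; each
    group also gets its own condition model with pairwise contrasts, and
    Welch t-tests check that the groups do not differ on other covariates.
    """
    from .associations import welch_ttest  # local import avoids cycle at import time

    groups = median_split(profiles)
    counts = groups["wordgroup"].value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("degenerate group sizes after median split")

    data = cell_means.merge(groups, on="participant_id").dropna(subset=["ppd"])
    warns: list = []
    full = _fit_mixedlm("ppd ~ C(snr) * wordgroup", data, reml=False)
    add = _fit_mixedlm("ppd ~ C(snr) + wordgroup", data, reml=False)
    df_int = data["snr"].nunique() - 1
    lrt = _lrt(full.llf, add.llf, df=df_int)
    fit = _fit_mixedlm("ppd ~ C(snr) * wordgroup", data, reml=True)
    _check_singular(fit, warns)
    k = len(fit.fe_params)
    cov = _mixedlm_fixed_cov(fit, k)
    fe = pd.DataFrame({"term": list(fit.fe_params.index),
                       "beta": np.asarray(fit.fe_params),
                       "se": np.sqrt(np.diag(cov))})
    fe["z"] = fe["beta"] / fe["se"]
    fe["p"] = 2.0 * stats.norm.sf(np.abs(fe["z"]))
    interaction = ModelFit(fixed_effects=fe, lrt=lrt, family="linear",
                           formula_descr="ppd ~ C(snr) * wordgroup + (1 | participant)",
                           contrasts=None, warnings=warns)

    per_group = {}
    for g, sub in data.groupby("wordgroup"):
        per_group[g] = fit_condition_model(sub[["participant_id", "snr", "ppd"]])

    prof = profiles.merge(groups, on="participant_id")
    rows = []
    for cov_name in covariates:
        if cov_name not in prof.columns:
            continue
        a = prof.loc[prof["wordgroup"] == "low", cov_name].to_numpy(dtype=float)
        b = prof.loc[prof["wordgroup"] == "high", cov_name].to_numpy(dtype=float)
        t, df, p = welch_ttest(a, b)
        rows.append({"covariate": cov_name, "t": t, "df": df, "p": p})
    covariate_tests = pd.DataFrame(rows)
    return WordGroupResult(groups=groups, interaction=interaction,
                           per_group=per_group, covariate_tests=covariate_tests)
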