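"""Correlation battery between individual factors and psychometric shape.

Reproduces the analysis logic of the individual-differences table: for each
of 12 participant-level factors against each of the two shape parameters
(mean PPD and the quadratic coefficient of the PPD-vs-SNR fit), the method
is Pearson's r when both variables are continuous and pass a normality
screen, Spearman's rho when either is bounded/ordinal (e.g. percent-correct
scores) or non-normal.  p values are Bonferroni-corrected at a configurable
family size (default 24 = 12 factors x 2 shape parameters).

Also provides Welch's unequal-variance t-test (used for group profile
checks) and the exploratory per-group moderated regressions of shape
parameters on inhibition/working-memory scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .types import CorrelationResult


# ---------------------------------------------------------------------------
# variable metadata and method choice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarMeta:
    """A variable plus the flag driving correlation-method choice."""

    name: str
    bounded: bool    # True for bounded/ordinal scores (percent scales, counts)


#: The 12 individual-difference factors of the association battery, with
#: their bounded/ordinal flags.  Percent-bounded scores, proportion scores
#: and item counts are non-continuous by the selection rule.
FACTOR_META = (
    VarMeta("age", False),
    VarMeta("ci_duration", False),
    VarMeta("word_recognition", True),
    VarMeta("t_level", False),
    VarMeta("qol_total", True),
    VarMeta("tlx_mean", True),
    VarMeta("sentence_correct", True),
    VarMeta("matrices_correct", True),
    VarMeta("stroop_interference", True),
    VarMeta("stroop_control_rt", False),
    VarMeta("nback_dprime", False),
    VarMeta("smrt_threshold", False),
)

SHAPE_META = (VarMeta("mean_ppd", False), VarMeta("quad_coef", False))


def choose_method(x: VarMeta, x_values, y: VarMeta, y_values,
                  normality_alpha: float = 0.05) -> str:
    """'spearman' iff either variable is bounded/ordinal or fails a
    Shapiro-Wilk normality screen; 'pearson' otherwise."""
    if x.bounded or y.bounded:
        return "spearman"
    for vals in (x_values, y_values):
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= 3 and np.ptp(v) > 0:
            if stats.shapiro(v).pvalue < normality_alpha:
                return "spearman"
    return "pearson"


# ---------------------------------------------------------------------------
# correlation core
# ---------------------------------------------------------------------------

#: sample sizes up to which Spearman p-values use the permutation null
SPEARMAN_EXACT_N_MAX = 30


@lru_cache(maxsize=8)
def _spearman_null_abs_rho(n: int, n_samples: int = 1_000_000) -> np.ndarray:
    """Sorted |rho| draws from the exact permutation null at sample size n.

    The t approximation for Spearman's rho is anticonservative in the far
    tails at small n — exactly where Bonferroni-corrected decisions live —
    so small-sample p-values are taken from this cached Monte-Carlo
    permutation distribution (fixed internal seed; deterministic).
    """
    rng = np.random.default_rng(987654321)
    c = np.arange(n, dtype=float)
    c -= c.mean()
    denom = float((c ** 2).sum())
    out = np.empty(n_samples)
    filled = 0
    chunk = 200_000
    while filled < n_samples:
        k = min(chunk, n_samples - filled)
        u = rng.random((k, n))
        ranks = np.argsort(np.argsort(u, axis=1), axis=1).astype(float)
        rho = ((ranks - (n - 1) / 2.0) * c).sum(axis=1) / denom
        out[filled:filled + k] = np.abs(rho)
        filled += k
    out.sort()
    return out


def _spearman_perm_p(rho: float, n: int) -> float:
    null = _spearman_null_abs_rho(n)
    m = null.size
    count = m - int(np.searchsorted(null, abs(rho) - 1e-12, side="left"))
    return (count + 1) / (m + 1)


def correlate(x, y, method: str, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson or Spearman correlation with the field's test statistic.

    Pearson reports t = r sqrt((n-2)/(1-r^2)); Spearman reports the
    S = (1 - rho)(n^3 - n)/6 statistic (midrank ties), both with two-sided p.
    Pairwise-complete observations only; needs n >= 3 and non-degenerate
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")

    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        denom = max(1.0 - r * r, np.finfo(float).tiny)
        t = r * np.sqrt((n - 2) / denom)
        return CorrelationResult(x_name, y_name, "pearson", float(r), float(t),
                                 float(p), float(p), n)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        if n <= SPEARMAN_EXACT_N_MAX:
            p = _spearman_perm_p(float(rho), n)
        s = (1.0 - rho) * (n ** 3 - n) / 6.0
        return CorrelationResult(x_name, y_name, "spearman", float(rho), float(s),
                                 float(p), float(p), n)
    raise ValueError(f"unknown method: {method}")


def bonferroni(p_values, m: int) -> np.ndarray:
    """Elementwise p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("family size must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# the factor x shape grid
# ---------------------------------------------------------------------------

def correlation_table(
    profiles: pd.DataFrame,
    shape: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    m: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The 12-factor x 2-shape-parameter correlation grid.

    ``profiles`` supplies the stable covariates; ``behavior`` (optional)
    supplies per-participant task summaries (sentence_correct, tlx_mean).
    Factors missing from the merged table are reported with NaN results
    rather than silently dropped.  ``m`` defaults to the number of testable
    cells (nominally 24); it is recorded in the output because it decides
    which entries survive correction.
    """
    merged = profiles.merge(shape, on="participant_id")
    if behavior is not None:
        merged = merged.merge(behavior, on="participant_id", how="left")

    cells = []
    for fmeta in FACTOR_META:
        for smeta in SHAPE_META:
            cells.append((fmeta, smeta))
    if m is None:
        m = len(cells)

    rows = []
    for fmeta, smeta in cells:
        base = {"factor": fmeta.name, "target": smeta.name, "m": m}
        if fmeta.name not in merged.columns or smeta.name not in merged.columns:
            rows.append({**base, "method": None, "statistic": np.nan,
                         "test_stat": np.nan, "p": np.nan, "p_adj": np.nan,
                         "n": 0, "significant": False,
                         "note": "column missing"})
            continue
        xv = merged[fmeta.name].to_numpy(dtype=float)
        yv = merged[smeta.name].to_numpy(dtype=float)
        method = choose_method(fmeta, xv, smeta, yv)
        try:
            res = correlate(xv, yv, method, fmeta.name, smeta.name)
        except ValueError as exc:
            rows.append({**base, "method": method, "statistic": np.nan,
                         "test_stat": np.nan, "p": np.nan, "p_adj": np.nan,
                         "n": 0, "significant": False, "note": str(exc)})
            continue
        p_adj = float(bonferroni([res.p], m)[0])
        rows.append({**base, "method": res.method, "statistic": res.statistic,
                     "test_stat": res.test_stat, "p": res.p, "p_adj": p_adj,
                     "n": res.n, "significant": p_adj < alpha, "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def welch_ttest(group_a, group_b) -> tuple[float, float, float]:
    """Unequal-variance two-sample t with Satterthwaite df, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# exploratory per-group moderated regressions
# ---------------------------------------------------------------------------

def moderated_regressions(
    shape: pd.DataFrame,
    profiles: pd.DataFrame,
    groups: pd.DataFrame,
    predictors: tuple = ("stroop_interference", "nback_dprime"),
    outcomes: tuple = ("quad_coef", "mean_ppd"),
) -> pd.DataFrame:
    """Per-wordgroup simple regressions of shape parameters on cognition.

    For each group separately, OLS of each shape outcome on each predictor
    (slope, SE, two-sided p).  Exploratory: p values are intentionally
    uncorrected, and the output flags them as such.  Raises on group n < 3
    or constant predictors.
    """
    data = shape.merge(profiles, on="participant_id").merge(groups, on="participant_id")
    rows = []
    for g, sub in data.groupby("wordgroup"):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 participants")
        for pred in predictors:
            x = sub[pred].to_numpy(dtype=float)
            if np.ptp(x[np.isfinite(x)]) == 0:
                raise ValueError(f"constant predictor {pred!r} in group {g!r}")
            for out in outcomes:
                y = sub[out].to_numpy(dtype=float)
                keep = np.isfinite(x) & np.isfinite(y)
                res = stats.linregress(x[keep], y[keep])
                t = res.slope / res.stderr if res.stderr > 0 else np.nan
                rows.append({
                    "wordgroup": g, "predictor": pred, "outcome": out,
                    "beta": float(res.slope), "se": float(res.stderr),
                    "t": float(t), "p": float(res.pvalue),
                    "n": int(keep.sum()), "exploratory_uncorrected": True,
                })
    return pd.DataFrame(rows)
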