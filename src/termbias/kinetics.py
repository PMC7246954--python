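"""Protein decay-rate fitting from reporter shut-off time courses.

After transcription of a luciferase reporter is shut off at t = 0, the
luminescence L(t) of each C-terminal variant decays as L(0) * exp(-d t)
with first-order degradation rate d (per hour).  d is estimated per
replicate by ordinary least squares of ln(L(t)/L(0)) on t over the
post-shut-off time points, with a free intercept (t = 0 itself is excluded
from the regression).  Half-life is ln 2 / d.

Steady-state expression X before shut-off reflects the synthesis/
degradation balance X = s/d; regressing X on 1/d across variants measures
how much of the expression variation degradation alone explains.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

FIT_TIMES = (2.0, 4.0, 6.0, 8.0)


def normalize_series(
    ts: pd.DataFrame, reference: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize luminescence time courses per replicate and extract steady states.

    ``ts`` has columns variant, replicate, time_h, luminescence and
    optionally cat_norm (constitutive-marker normalization scalar, default
    1).  The decay track of each (variant, replicate) is divided by its
    t = 0 luminescence.  The steady-state value is the t = 0 luminescence
    divided by cat_norm and, when ``reference`` names a variant, expressed
    relative to that variant's mean steady state.

    Returns (decay DataFrame with a ``norm_lum`` column, steady-state
    DataFrame with columns variant, replicate, steady_state).
    """
    df = ts.copy()
    if "cat_norm" not in df:
        df["cat_norm"] = 1.0
    bad = df[df["luminescence"] <= 0]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"nonpositive luminescence for variant {first['variant']} "
            f"replicate {first['replicate']} at t={first['time_h']}"
        )
    steady_rows = []
    norm = np.empty(len(df))
    for (variant, rep), idx in df.groupby(["variant", "replicate"]).groups.items():
        sub = df.loc[idx]
        t0 = sub[sub["time_h"] == 0]
        if t0.empty:
            raise ValueError(f"missing t=0 point for {variant} replicate {rep}")
        l0 = float(t0["luminescence"].iloc[0])
        norm[df.index.get_indexer(idx)] = df.loc[idx, "luminescence"] / l0
        steady_rows.append(
            {
                "variant": variant,
                "replicate": rep,
                "steady_state": l0 / float(t0["cat_norm"].iloc[0]),
            }
        )
    df["norm_lum"] = norm
    steady = pd.DataFrame(steady_rows)
    if reference is not None:
        ref = steady.loc[steady["variant"] == reference, "steady_state"].mean()
        if not ref > 0:
            raise ValueError(f"reference variant {reference!r} has no positive steady state")
        steady["steady_state"] /= ref
    return df, steady


def fit_decay(
    ts: pd.DataFrame, fit_times: Sequence[float] = FIT_TIMES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-linear decay fits per (variant, replicate) and per-variant summary.

    Fits ln(norm_lum) = intercept - d * t over ``fit_times`` by OLS with a
    free intercept; requires >= 3 positive points.  d <= 0 (no decay) is
    reported with a warning and an infinite half-life.  Returns
    (per-replicate fits, per-variant summary with mean and SD of d).
    """
    if "norm_lum" not in ts:
        ts, _ = normalize_series(ts)
    rows = []
    for (variant, rep), sub in ts.groupby(["variant", "replicate"]):
        pts = sub[sub["time_h"].isin(fit_times) & (sub["norm_lum"] > 0)]
        if len(pts) < 3:
            logger.warning("excluding %s replicate %s: %d usable points", variant, rep, len(pts))
            continue
        t = pts["time_h"].to_numpy(float)
        y = np.log(pts["norm_lum"].to_numpy(float))
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        d = -slope
        if d <= 0:
            logger.warning("%s replicate %s: no decay (d = %.3g)", variant, rep, d)
        rows.append(
            {
                "variant": variant,
                "replicate": rep,
                "d": d,
                "intercept": intercept,
                "r2": r2,
                "half_life": half_life(d),
            }
        )
    fits = pd.DataFrame(rows)
    if fits.empty:
        raise ValueError("no (variant, replicate) series could be fitted")
    summary = (
        fits.groupby("variant", as_index=False)
        .agg(d_mean=("d", "mean"), d_sd=("d", "std"), n_replicates=("d", "size"))
    )
    summary["half_life"] = summary["d_mean"].map(half_life)
    return fits, summary


def half_life(d: float) -> float:
    """Half-life ln 2 / d in hours; infinite when d <= 0 (no decay)."""
    if d <= 0:
        return math.inf
    return math.log(2) / d


def steady_state_fit(X: Sequence[float], d: Sequence[float]) -> dict:
    """OLS regression of steady-state expression X on 1/d across variants.

    Under constant synthesis rate s, X = s/d, so the slope estimates s and
    the adjusted R^2 measures how much expression variation degradation
    explains.  Requires >= 3 variants with d > 0.
    """
    X = np.asarray(X, float)
    d = np.asarray(d, float)
    if len(X) < 3 or len(X) != len(d):
        raise ValueError("need >= 3 matched (X, d) points")
    if np.any(d <= 0):
        raise ValueError("all degradation rates must be positive")
    design = sm.add_constant(1.0 / d)
    model = sm.OLS(X, design).fit()
    return {
        "s": float(model.params[1]),
        "intercept": float(model.params[0]),
        "adj_r2": float(model.rsquared_adj),
        "r2": float(model.rsquared),
        "model": model,
    }


def fold_difference(x_a: float, x_b: float) -> float:
    """Expression fold difference x_a / x_b."""
    if x_b == 0:
        raise ZeroDivisionError("zero denominator in fold difference")
    return x_a / x_b


def group_compare(
    values_a: Iterable[float], values_b: Iterable[float], equal_var: bool = True
) -> dict:
    """Two-sided independent t-test between two groups of measurements."""
    a = np.asarray(list(values_a), float)
    b = np.asarray(list(values_b), float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "p": 1.0}
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p)}
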