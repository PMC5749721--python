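"""Time-course normalization, drift, endpoint change and concordance fits.

Repeated FLIM measurements of the same cells (every minute for ten
minutes here) expose photophysical instability: intensity bleaches,
and some acceptors photo-damage so the donor lifetime drifts upward as
less energy is transferred.  The summaries in this module quantify that:

* per-cell traces are normalised to the across-cell mean of the t = 0
  values of their experimental day, so days of different absolute scale
  become comparable;
* a straight line through the mean normalised trace gives a drift slope
  (fraction per minute) with its standard error;
* the distribution of per-cell (t = 10) − (t = 0) changes is summarised by
  its mean, median and the 10/25/75/90th percentiles (linear interpolation
  between closest ranks);
* Spearman rank correlation tests whether lifetime variability tracks
  intensity variability across constructs;
* predicted vs measured efficiencies are compared by a least-squares line
  through the origin, b = Σxy/Σx², with R² = 1 − Σ(y−bx)²/Σy² (the
  no-intercept definition) and a t-based 95 % CI on the gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimecourseSummary",
    "normalize_traces",
    "drift_slope",
    "endpoint_change_summary",
    "variability_correlation",
    "predicted_vs_measured_fit",
    "percent_sd",
]

PERCENTILES = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class TimecourseSummary:
    """Stability summary of one construct / platform / quantity."""

    construct: str
    platform: str
    quantity: str
    n_cells: int
    endpoint_mean: float
    endpoint_median: float
    endpoint_percentiles: dict[int, float]
    total_sd: float


def normalize_traces(
    cells: pd.DataFrame, value_column: str = "lifetime_ns"
) -> pd.DataFrame:
    """Normalise each cell's trace to its day's mean t = 0 value.

    Returns a copy with an added ``normalized`` column; days without any
    t = 0 measurement are dropped with a warning.  Idempotent: running it
    on already-normalised values changes nothing (each day's t = 0 mean is
    then exactly 1).
    """
    required = {"cell_id", "day", "timepoint_min", value_column}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    out = []
    for day, group in cells.groupby("day"):
        t0 = group.loc[group["timepoint_min"] == 0, value_column]
        if t0.empty:
            warnings.warn(f"day {day} has no t = 0 measurement: excluded", stacklevel=2)
            continue
        scale = t0.mean()
        g = group.copy()
        g["normalized"] = g[value_column] / scale
        out.append(g)
    if not out:
        raise ValueError("no day has a t = 0 measurement")
    return pd.concat(out, ignore_index=True)


def drift_slope(trace_set: pd.DataFrame) -> tuple[float, float]:
    """OLS slope (per minute) and SE of the mean normalised trace.

    ``trace_set`` must carry ``timepoint_min`` and ``normalized`` columns
    (see :func:`normalize_traces`); the line is fitted through the
    across-cell mean at each timepoint.
    """
    mean_trace = trace_set.groupby("timepoint_min")["normalized"].mean()
    if len(mean_trace) < 3:
        raise ValueError("need at least 3 timepoints for a drift fit")
    res = stats.linregress(mean_trace.index.to_numpy(float), mean_trace.to_numpy())
    return float(res.slope), float(res.stderr)


def endpoint_change_summary(
    trace_set: pd.DataFrame,
    construct: str = "",
    platform: str = "",
    quantity: str = "lifetime",
    t_end: float = 10.0,
) -> TimecourseSummary:
    """Distribution of per-cell (t = end) − (t = 0) normalised changes."""
    wide = trace_set.pivot_table(
        index="cell_id", columns="timepoint_min", values="normalized"
    )
    if 0 not in wide.columns or t_end not in wide.columns:
        raise ValueError(f"traces must contain both t = 0 and t = {t_end}")
    change = (wide[t_end] - wide[0]).dropna().to_numpy()
    if change.size == 0:
        raise ValueError("no cell has both endpoint measurements")
    percentiles = {
        p: float(np.percentile(change, p, method="linear")) for p in PERCENTILES
    }
    return TimecourseSummary(
        construct=construct,
        platform=platform,
        quantity=quantity,
        n_cells=int(change.size),
        endpoint_mean=float(change.mean()),
        endpoint_median=percentiles[50],
        endpoint_percentiles=percentiles,
        total_sd=float(change.std(ddof=1)) if change.size > 1 else 0.0,
    )


def percent_sd(values: Sequence[float]) -> float:
    """Across-cell standard deviation as a percentage of the mean."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean is zero; %SD undefined")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def variability_correlation(
    sd_lifetime_percent: Sequence[float],
    sd_intensity_percent: Sequence[float],
) -> tuple[float, float]:
    """Spearman rank correlation of lifetime %SD against intensity %SD.

    Returns (rho, two-sided p).  Used to test whether cells that vary in
    expression level (intensity) also vary in lifetime — across the
    benchmark constructs they do not.
    """
    x = np.asarray(sd_lifetime_percent, dtype=float)
    y = np.asarray(sd_intensity_percent, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def predicted_vs_measured_fit(
    predicted_E: pd.Series | dict[str, float],
    measured_E: pd.Series | dict[str, float],
    exclude: Sequence[str] = (),
) -> dict[str, float]:
    """Through-origin regression of measured on predicted efficiencies.

    ``predicted_E`` and ``measured_E`` map pair names to efficiencies
    (fractions or percent — any common scale); pairs named in ``exclude``
    (e.g. known outliers) are dropped before fitting.  Returns a dict with
    ``gradient``, ``r_squared`` (1 − Σ(y−bx)²/Σy², no-intercept
    definition), ``ci_low``/``ci_high`` (95 %) and ``n_pairs``.
    """
    pred = pd.Series(predicted_E, dtype=float)
    meas = pd.Series(measured_E, dtype=float)
    common = [k for k in pred.index if k in meas.index and k not in set(exclude)]
    if len(common) < 3:
        raise ValueError("need at least 3 pairs after exclusion")
    x = pred[common].to_numpy()
    y = meas[common].to_numpy()
    sxx = float(np.sum(x**2))
    if sxx == 0:
        raise ValueError("all predicted efficiencies are zero")
    b = float(np.sum(x * y) / sxx)
    resid = y - b * x
    syy = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else float("nan")
    n = len(common)
    se_b = float(np.sqrt(np.sum(resid**2) / (n - 1) / sxx))
    t_crit = float(stats.t.ppf(0.975, n - 1))
    return {
        "gradient": b,
        "r_squared": r2,
        "se": se_b,
        "ci_low": b - t_crit * se_b,
        "ci_high": b + t_crit * se_b,
        "n_pairs": n,
    }
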