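"""FRET efficiency from lifetimes, Z′-factor assay scoring, and derived metrics.

Per-cell measurements are carried as tidy :class:`pandas.DataFrame` tables
with one row per cell × timepoint (see :data:`CELL_COLUMNS`): this is the
same table the synthetic generator emits and the readers in
:mod:`flimpair.io` load.

The central statistic is the Z′-factor of Zhang's assay-quality family,

    Z′ = 1 − 3 (σ_max + σ_min) / |μ_max − μ_min|,

where the "max" signal is the donor-alone lifetime population and the
"min" signal the donor lifetime in the presence of the acceptor.  Z′ ≤ 1
always; values above ~0.5 indicate a pair whose lifetime shift is well
separated from the measurement spread, and negative values a pair whose
shift drowns in its own variability.

Evaluation follows the study design the statistics assume: each
experimental day is one repeat, μ and σ are computed over the cells of
that day (σ with the n−1 denominator), FRET efficiency is taken against
the *day-matched* donor-alone mean, and the day-level Z′ and E are then
summarised as mean ± SD across days.  "Static" mode uses only the t = 0
measurements; "dynamic" mode pools every timepoint of every cell in the
day, so any temporal drift inflates σ and honestly degrades Z′.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CELL_COLUMNS",
    "AssayEvaluation",
    "efficiency_from_lifetimes",
    "z_factor",
    "evaluate_assay",
    "concordance",
    "sensitivity_ps_per_percent",
    "stimulation_response",
    "significance_stars",
]

#: Required columns of a per-cell measurement table.
CELL_COLUMNS = (
    "cell_id",
    "dish_id",
    "day",
    "platform",
    "construct",
    "timepoint_min",
    "intensity",
    "lifetime_ns",
)


@dataclass(frozen=True)
class AssayEvaluation:
    """Across-day summary of one pair on one platform.

    ``E_*`` are fractions (0.241 = 24.1 %); ``mode`` is ``"static"``
    (t = 0 only) or ``"dynamic"`` (all timepoints pooled per day).
    """

    pair: str
    platform: str
    mode: str
    E_mean: float
    E_sd: float
    Zprime_mean: float
    Zprime_sd: float
    n_days: int

    def __post_init__(self) -> None:
        if self.Zprime_mean > 1.0 + 1e-12:
            raise ValueError("Z' cannot exceed 1")


def efficiency_from_lifetimes(tau_donor: float, tau_pair: float) -> float:
    """FRET efficiency E = 1 − τ_DA / τ_D from donor-alone and pair lifetimes.

    A pair lifetime longer than the donor-alone lifetime gives a negative
    E; this is retained (with a warning) rather than clipped, since small
    negatives are an honest signature of measurement noise.
    """
    if tau_donor <= 0:
        raise ValueError("donor lifetime must be positive")
    E = 1.0 - tau_pair / tau_donor
    if E < 0:
        warnings.warn(
            f"pair lifetime {tau_pair} ns exceeds donor lifetime {tau_donor} ns: "
            f"negative efficiency {E:.3g} (noise)",
            stacklevel=2,
        )
    return E


def z_factor(
    mu_max: float, sigma_max: float, mu_min: float, sigma_min: float
) -> float:
    """Z′ = 1 − 3 (σ_max + σ_min) / |μ_max − μ_min|."""
    if sigma_max < 0 or sigma_min < 0:
        raise ValueError("standard deviations must be non-negative")
    if mu_max == mu_min:
        raise ValueError("undefined separation: mu_max == mu_min")
    return 1.0 - 3.0 * (sigma_max + sigma_min) / abs(mu_max - mu_min)


def _require_columns(df: pd.DataFrame, context: str) -> None:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{context}: missing columns {missing}")


def _select_mode(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "static":
        return df[df["timepoint_min"] == 0]
    if mode == "dynamic":
        return df
    raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")


def evaluate_assay(
    donor_cells: pd.DataFrame,
    pair_cells: pd.DataFrame,
    mode: str = "static",
    pair_name: str | None = None,
) -> AssayEvaluation:
    """Day-wise Z′ and FRET efficiency for one pair against its donor control.

    For each day present in both tables, the donor-alone lifetimes form
    the max-signal population and the pair lifetimes the min-signal
    population; Z′ and E (against the day-matched donor mean) are computed
    per day and then summarised across days as mean ± SD.
    """
    _require_columns(donor_cells, "donor_cells")
    _require_columns(pair_cells, "pair_cells")
    platforms = set(donor_cells["platform"]) | set(pair_cells["platform"])
    if len(platforms) != 1:
        raise ValueError(f"donor and pair tables must share one platform: {platforms}")
    platform = platforms.pop()

    donor = _select_mode(donor_cells, mode)
    pair = _select_mode(pair_cells, mode)
    days = sorted(set(donor["day"]) & set(pair["day"]))
    skipped = sorted((set(donor["day"]) | set(pair["day"])) - set(days))
    if skipped:
        warnings.warn(f"days without donor/pair pairing skipped: {skipped}", stacklevel=2)
    z_days, e_days = [], []
    for day in days:
        d = donor.loc[donor["day"] == day, "lifetime_ns"]
        p = pair.loc[pair["day"] == day, "lifetime_ns"]
        if len(d) < 2 or len(p) < 2:
            warnings.warn(f"day {day}: fewer than 2 cells in an arm, skipped", stacklevel=2)
            continue
        mu_max, sd_max = d.mean(), d.std(ddof=1)
        mu_min, sd_min = p.mean(), p.std(ddof=1)
        z_days.append(z_factor(mu_max, sd_max, mu_min, sd_min))
        e_days.append(efficiency_from_lifetimes(mu_max, mu_min))
    if not z_days:
        raise ValueError("no usable days with both donor and pair measurements")
    z_arr, e_arr = np.asarray(z_days), np.asarray(e_days)
    name = pair_name or str(pair_cells["construct"].iloc[0])
    return AssayEvaluation(
        pair=name,
        platform=str(platform),
        mode=mode,
        E_mean=float(e_arr.mean()),
        E_sd=float(e_arr.std(ddof=1)) if e_arr.size > 1 else 0.0,
        Zprime_mean=float(z_arr.mean()),
        Zprime_sd=float(z_arr.std(ddof=1)) if z_arr.size > 1 else 0.0,
        n_days=len(z_days),
    )


def concordance(
    eval_fd: AssayEvaluation, eval_td: AssayEvaluation
) -> tuple[tuple[float, float], float]:
    """Cross-platform agreement of a pair's Z′ values.

    Returns ``((Z'_FD, Z'_TD), d)`` where ``d`` is the perpendicular
    distance of the point from the identity line, |Z′_FD − Z′_TD| / √2; a
    pair behaving identically on both platforms scores 0.
    """
    if eval_fd.pair != eval_td.pair:
        raise ValueError("concordance compares the same pair on two platforms")
    if eval_fd.mode != eval_td.mode:
        raise ValueError("concordance requires matching static/dynamic modes")
    z = (eval_fd.Zprime_mean, eval_td.Zprime_mean)
    return z, abs(z[0] - z[1]) / math.sqrt(2.0)


def sensitivity_ps_per_percent(tau_donor: float) -> float:
    """Lifetime change per percentage point of FRET efficiency, in ps.

    Since Δτ = τ_D · ΔE, one percentage point of efficiency moves the
    measured lifetime by τ_D × 1000 / 100 = 10·τ_D picoseconds: the
    analytic basis for preferring long-lifetime donors.
    """
    if tau_donor <= 0:
        raise ValueError("donor lifetime must be positive")
    return 10.0 * tau_donor


def significance_stars(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.005."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stimulation_response(
    timecourse: pd.DataFrame,
    donor_controls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-timepoint biosensor response to a stimulation delivered at t = 0.

    ``timecourse`` holds sensor-expressing cells measured at timepoints
    {−2, −1, 0, +1, +2} minutes around the stimulus; ``donor_controls``
    holds donor-alone cells under the same protocol.  For each timepoint
    the lifetime change against each cell's own t = 0 value is averaged
    (Δτ), the efficiency is computed against the time-matched donor-control
    mean, and pre- vs post-stimulation per-cell Δτ are compared with a
    two-sided Wilcoxon rank-sum test.

    Returns a frame indexed by timepoint with columns ``delta_tau_ns``,
    ``delta_tau_sd``, ``E``, ``p_value``, ``stars`` (the test p-value is
    attached to post-stimulation rows).
    """
    _require_columns(timecourse, "timecourse")
    _require_columns(donor_controls, "donor_controls")
    if 0 not in set(timecourse["timepoint_min"]):
        raise ValueError("timecourse has no t = 0 measurement")

    wide = timecourse.pivot_table(
        index="cell_id", columns="timepoint_min", values="lifetime_ns"
    )
    if 0 not in wide.columns:
        raise ValueError("timecourse has no t = 0 measurement")
    delta = wide.sub(wide[0], axis=0)

    donor_means = donor_controls.groupby("timepoint_min")["lifetime_ns"].mean()

    pre_cols = [c for c in delta.columns if c < 0]
    post_cols = [c for c in delta.columns if c > 0]
    pre = delta[pre_cols].to_numpy().ravel() if pre_cols else np.array([])
    pre = pre[~np.isnan(pre)]

    rows = []
    for tp in sorted(wide.columns):
        d = delta[tp].dropna()
        tau_mean = wide[tp].mean()
        if tp in donor_means.index:
            E = efficiency_from_lifetimes(float(donor_means[tp]), float(tau_mean))
        else:
            E = np.nan
        p_val = np.nan
        if tp in post_cols and pre.size and d.size:
            p_val = float(stats.ranksums(pre, d.to_numpy()).pvalue)
        rows.append(
            {
                "timepoint_min": tp,
                "delta_tau_ns": float(d.mean()),
                "delta_tau_sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "E": E,
                "p_value": p_val,
                "stars": significance_stars(p_val) if not math.isnan(p_val) else "",
            }
        )
    return pd.DataFrame(rows).set_index("timepoint_min")


def empirical_sensitivity_ps_per_percent(
    delta_tau_ns: Sequence[float], delta_E: Sequence[float]
) -> float:
    """Measured ps-per-%E sensitivity, Δτ regressed through the origin on ΔE.

    Empirical counterpart of :func:`sensitivity_ps_per_percent`; ΔE in
    fractional units (0.05 = 5 %E).
    """
    dt = np.asarray(delta_tau_ns, dtype=float) * 1e3  # ps
    de = np.asarray(delta_E, dtype=float) * 100.0  # %E
    denom = np.sum(de**2)
    if denom == 0:
        raise ValueError("all efficiency changes are zero")
    return float(abs(np.sum(dt * de) / denom))
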