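"""ROI kinetics of tumor StO2 during photodynamic therapy.

The bulk readout of a PDT monitoring recording is the tumor-ROI mean StO2
versus time.  The trace is median-filtered (order 15 by default), normalized
so that the 5-min pre-irradiation baseline averages 100 %, and summarized by
the mean moving slope over the first 5 min of light (the oxygen depletion
rate, in normalized-% per minute) and by the "end of active PDT": the time at
which photochemical oxygen consumption stops depleting StO2, detected as the
trace minimum over the light interval.  A Severinghaus oxygen-dissociation
conversion links StO2 thresholds to pO2, and group depletion rates are
compared with one-way ANOVA plus Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NormalizationError, StatisticsError, ValidationError
from .unmixing import OximetryMaps

__all__ = [
    "ROIMask",
    "PDTTimeline",
    "StO2Trace",
    "RateSummary",
    "GroupComparison",
    "roi_mean_trace",
    "median_filter_trace",
    "normalize_trace",
    "moving_slope",
    "mean_depletion_rate",
    "detect_active_pdt_end",
    "severinghaus_so2",
    "inverse_severinghaus",
    "compare_group_rates",
    "build_trace",
]


@dataclass(frozen=True)
class ROIMask:
    """Tumor region of interest annotated on the co-registered ultrasound.

    ``allow_empty`` exists for degenerate derived regions (e.g. one half of a
    single-column ROI split); primary ROIs must contain at least one pixel.
    """

    mask: np.ndarray
    label: str = "tumor"
    allow_empty: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any() and not self.allow_empty:
            raise ValidationError("ROI must contain at least one pixel")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PDTTimeline:
    """Treatment milestones of one recording, in seconds from recording start.

    ``t_active_end`` is unset until detected from the trace.
    """

    t_baseline_start: float
    t_light_on: float
    t_light_off: float
    t_end: float
    t_active_end: float | None = None

    def __post_init__(self) -> None:
        ok = (
            self.t_baseline_start <= self.t_light_on < self.t_light_off
            <= self.t_end
        )
        if not ok:
            raise ValidationError(
                "timeline must satisfy baseline <= light_on < light_off <= end"
            )
        if self.t_active_end is not None and not (
            self.t_light_on <= self.t_active_end <= self.t_end
        ):
            raise ValidationError("t_active_end outside [light_on, end]")


@dataclass
class StO2Trace:
    """ROI-mean StO2 time series with raw/filtered/normalized channels.

    Frames without any valid ROI pixel carry NaN and are skipped (never
    imputed) by filtering and normalization.
    """

    t: np.ndarray
    raw: np.ndarray
    timeline: PDTTimeline
    hbt_raw: np.ndarray | None = None
    filtered: np.ndarray | None = None
    normalized: np.ndarray | None = None


@dataclass(frozen=True)
class RateSummary:
    """Per-subject depletion rates of one treatment group."""

    group: str
    per_subject_rate: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.per_subject_rate)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across groups plus Tukey HSD pairwise table."""

    anova_f: float
    anova_p: float
    table: pd.DataFrame  # group1, group2, mean_diff, p_adj, significant


def roi_mean_trace(
    maps_seq: Sequence[OximetryMaps],
    roi: ROIMask,
    timeline: PDTTimeline,
) -> StO2Trace:
    """ROI-mean StO2 and HbT per frame, excluding zero (masked) pixels.

    The exclusion matters: noise-floor pixels are stored as 0, and averaging
    them in would bias the tumor mean toward 0 as vessels shut down.
    """
    if not len(maps_seq):
        raise ValidationError("need at least one frame")
    roi_m = roi.mask
    t = np.array([m.t for m in maps_seq], dtype=float)
    raw = np.full(len(maps_seq), np.nan)
    hbt = np.full(len(maps_seq), np.nan)
    for i, m in enumerate(maps_seq):
        if m.sto2.shape != roi_m.shape:
            raise ValidationError("ROI shape does not match frames")
        valid = roi_m & m.mask
        if valid.any():
            raw[i] = m.sto2[valid].mean()
            hbt[i] = m.hbt[valid].mean()
    return StO2Trace(t=t, raw=raw, hbt_raw=hbt, timeline=timeline)


def median_filter_trace(values: np.ndarray, order: int = 15) -> np.ndarray:
    """Sliding-window median of length ``order`` with truncated edge windows.

    At the edges the window shrinks to the in-bounds samples (no zero
    padding, which would bias the 100 % baseline downward at recording
    start).  NaN samples are ignored inside windows and preserved in place.
    """
    v = np.asarray(values, dtype=float)
    if order % 2 == 0 or order < 1:
        raise ValidationError("filter order must be odd and >= 1")
    if order > v.size:
        raise ValidationError("filter order exceeds series length")
    half = order // 2
    out = np.full_like(v, np.nan)
    for i in range(v.size):
        if np.isnan(v[i]):
            continue
        win = v[max(0, i - half) : i + half + 1]
        win = win[~np.isnan(win)]
        out[i] = np.median(win)
    return out


def normalize_trace(
    filtered: np.ndarray, t: np.ndarray, timeline: PDTTimeline
) -> np.ndarray:
    """Scale the filtered trace so the pre-light baseline averages 100 %.

    The scale factor is 100 divided by the mean over the baseline window
    [t_baseline_start, t_light_on); it removes inter-subject variation in
    starting oxygenation.
    """
    v = np.asarray(filtered, dtype=float)
    tv = np.asarray(t, dtype=float)
    sel = (tv >= timeline.t_baseline_start) & (tv < timeline.t_light_on)
    base = v[sel]
    base = base[~np.isnan(base)]
    if base.size == 0:
        raise NormalizationError("no samples in the baseline window")
    mean = base.mean()
    if mean <= 0:
        raise NormalizationError("baseline mean must be positive")
    return v * (100.0 / mean)


def moving_slope(
    values: np.ndarray,
    t: np.ndarray,
    window: int = 15,
) -> np.ndarray:
    """Per-index least-squares slope over a centered window, in %/min.

    The window truncates at the series edges; NaN samples are dropped within
    each window, and indices with fewer than two finite samples return NaN.
    """
    v = np.asarray(values, dtype=float)
    tm = np.asarray(t, dtype=float) / 60.0  # minutes
    if window < 2:
        raise ValidationError("slope window must be >= 2 samples")
    if window > v.size:
        raise ValidationError("slope window exceeds series length")
    half = window // 2
    out = np.full_like(v, np.nan)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        y = v[lo:hi]
        x = tm[lo:hi]
        ok = ~np.isnan(y)
        if ok.sum() < 2:
            continue
        y, x = y[ok], x[ok]
        xm, ym = x.mean(), y.mean()
        denom = ((x - xm) ** 2).sum()
        if denom == 0:
            continue
        out[i] = ((x - xm) * (y - ym)).sum() / denom
    return out


def mean_depletion_rate(
    trace: StO2Trace, duration_s: float = 300.0, window: int = 15
) -> float:
    """Mean moving slope of normalized StO2 over the first minutes of light.

    This is the per-subject depletion-rate statistic (normalized-% per
    minute); negative values mean oxygen depletion.
    """
    if trace.normalized is None:
        raise ValidationError("trace has no normalized channel")
    slopes = moving_slope(trace.normalized, trace.t, window=window)
    tl = trace.timeline
    sel = (trace.t >= tl.t_light_on) & (trace.t <= tl.t_light_on + duration_s)
    vals = slopes[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("no samples in the rate window")
    return float(vals.mean())


def detect_active_pdt_end(
    trace: StO2Trace,
    rule: str = "argmin",
    plateau_delta: float = 1.0,
    plateau_hold: int = 15,
) -> float:
    """Time at which photochemical oxygen depletion stops.

    ``argmin`` (default): the normalized-trace minimum over the light
    interval, ties broken earliest; a monotone decline through light-off
    returns light-off (active PDT lasting the whole light dose).  Invariant
    to positive affine rescaling of the trace.

    ``plateau``: the first sample after which the trace never drops more
    than ``plateau_delta`` normalized-% below its running minimum for
    ``plateau_hold`` consecutive samples — a sustained-non-decrease rule for
    traces whose minimum is ambiguous.
    """
    if trace.normalized is None:
        raise ValidationError("trace has no normalized channel")
    tl = trace.timeline
    sel = (trace.t >= tl.t_light_on) & (trace.t <= tl.t_light_off)
    vals = trace.normalized[sel]
    times = trace.t[sel]
    if vals.size == 0 or np.all(np.isnan(vals)):
        raise ValidationError("no samples in the light interval")
    if rule == "argmin":
        return float(times[np.nanargmin(vals)])
    if rule != "plateau":
        raise ValidationError(f"unknown endpoint rule {rule!r}")
    running_min = np.fmin.accumulate(vals)
    for i in range(vals.size - plateau_hold):
        ahead = vals[i + 1 : i + 1 + plateau_hold]
        ahead = ahead[~np.isnan(ahead)]
        if ahead.size and np.all(ahead >= running_min[i] - plateau_delta):
            return float(times[i])
    return float(times[-1])


def severinghaus_so2(pO2: float | np.ndarray) -> float | np.ndarray:
    """Severinghaus oxygen-dissociation curve: SO2 (%) at pO2 (mmHg).

    S = 100 * (23400 / (p^3 + 150 p) + 1)^-1; strictly increasing on p > 0.
    """
    p = np.asarray(pO2, dtype=float)
    if np.any(p <= 0):
        raise ValidationError("pO2 must be positive")
    s = 100.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return float(s) if np.isscalar(pO2) else s


def inverse_severinghaus(so2: float | np.ndarray) -> float | np.ndarray:
    """pO2 (mmHg) at saturation SO2 (%), the exact inverse of the curve.

    Solving S for p reduces to the depressed cubic p^3 + 150 p = 23400 S /
    (100 - S), whose single real root has a closed form.
    """
    s = np.asarray(so2, dtype=float)
    if np.any((s <= 0) | (s >= 100)):
        raise ValidationError("SO2 must lie strictly between 0 and 100 %")
    k = 23400.0 * s / (100.0 - s)
    disc = np.sqrt((k / 2.0) ** 2 + 50.0**3)
    p = np.cbrt(k / 2.0 + disc) + np.cbrt(k / 2.0 - disc)
    return float(p) if np.isscalar(so2) else p


def compare_group_rates(
    summaries: Sequence[RateSummary], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA across treatment groups, then Tukey HSD pairwise tests.

    Pairs with adjusted p < ``alpha`` are flagged significant.
    """
    if len(summaries) < 2:
        raise StatisticsError("need at least two groups")
    for s in summaries:
        if s.n < 2:
            raise StatisticsError(f"group '{s.group}' has fewer than 2 subjects")
    groups = [np.asarray(s.per_subject_rate, float) for s in summaries]
    f_stat, p_val = stats.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labels = np.concatenate(
        [np.repeat(s.group, s.n) for s in summaries]
    )
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    table = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(tk.pvalues, float),
            "significant": np.asarray(tk.reject, bool),
        }
    )
    return GroupComparison(anova_f=float(f_stat), anova_p=float(p_val), table=table)


def build_trace(
    maps_seq: Sequence[OximetryMaps],
    roi: ROIMask,
    timeline: PDTTimeline,
    filter_order: int = 15,
) -> StO2Trace:
    """Convenience: ROI means -> median filter -> baseline normalization."""
    trace = roi_mean_trace(maps_seq, roi, timeline)
    trace.filtered = median_filter_trace(trace.raw, order=filter_order)
    trace.normalized = normalize_trace(trace.filtered, trace.t, timeline)
    return trace
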