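"""Cardiorespiratory, lactate, jump and perceived-exertion summaries.

Breath-by-breath oxygen uptake is averaged over 5-s periods; VO2max is the
highest 30-s average of the incremental test and vVO2max the lowest stage
speed held for at least one minute that elicited it.  Jumping fatigue is the
percent height decrement relative to the pre-test jump; blood-lactate
accumulation is the post-set minus post-warm-up concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BreathTrace",
    "resample_breaths",
    "determine_vo2max_vvo2max",
    "percent_vo2max",
    "jump_percent_decrement",
    "delta_lactate",
]

BIN_S = 5.0
VO2MAX_WINDOW_S = 30.0
VVO2MAX_HOLD_S = 60.0
#: A stage "elicits VO2max" when its best 30-s mean is within this fraction.
VO2MAX_TOL = 0.02


@dataclass
class BreathTrace:
    """Timestamped breath-by-breath values (times in s, VO2 in mL/min/kg)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("breath times must be non-decreasing")


def resample_breaths(trace: BreathTrace, bin_s: float = BIN_S,
                     t_start: float = 0.0, t_end: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Block-average breaths over consecutive half-open ``bin_s`` bins.

    Returns (bin start times, bin means); bins without any breath are NaN.
    """
    if t_end is None:
        if trace.times.size == 0:
            raise ValueError("empty breath trace")
        t_end = float(trace.times.max())
    n_bins = int(np.ceil((t_end - t_start) / bin_s))
    if n_bins <= 0:
        raise ValueError("empty resampling interval")
    idx = np.floor((trace.times - t_start) / bin_s).astype(int)
    in_range = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[in_range], weights=trace.values[in_range], minlength=n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return t_start + bin_s * np.arange(n_bins), means


def _sliding_means(values: np.ndarray, width: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(values)))
    return (c[width:] - c[:-width]) / width


def determine_vo2max_vvo2max(bin_times: np.ndarray, bin_values: np.ndarray,
                             stage_speeds: np.ndarray, bin_s: float = BIN_S
                             ) -> tuple[float, float]:
    """(VO2max, vVO2max) from a 5-s-averaged incremental test.

    ``stage_speeds`` gives the prescribed speed (km/h) for each bin.  VO2max
    is the maximum sliding 30-s mean; vVO2max is the lowest stage speed held
    for at least 60 s whose own best 30-s mean reaches VO2max within 2%.
    """
    bin_values = np.asarray(bin_values, dtype=float)
    stage_speeds = np.asarray(stage_speeds, dtype=float)
    if bin_values.shape != stage_speeds.shape:
        raise ValueError("bin values and stage speeds must align")
    width = int(round(VO2MAX_WINDOW_S / bin_s))
    if bin_values.size < width:
        raise ValueError("incremental test shorter than the 30-s averaging window")
    valid = ~np.isnan(bin_values)
    if not valid.all():
        raise ValueError("incremental test contains empty bins")
    windows = _sliding_means(bin_values, width)
    vo2max = float(windows.max())

    hold_bins = int(round(VVO2MAX_HOLD_S / bin_s))
    candidates = []
    held_speeds = []
    for speed in np.unique(stage_speeds):
        mask = stage_speeds == speed
        if mask.sum() < hold_bins:
            continue
        held_speeds.append(float(speed))
        stage_vals = bin_values[mask]
        if stage_vals.size >= width:
            stage_peak = _sliding_means(stage_vals, width).max()
        else:
            stage_peak = stage_vals.mean()
        if stage_peak >= (1.0 - VO2MAX_TOL) * vo2max:
            candidates.append(float(speed))
    if candidates:
        return vo2max, min(candidates)
    # Measurement noise can push the single best 30-s window into the partial
    # final stage so that no completed stage reaches it within tolerance; fall
    # back to the last completed stage at or below the speed where the
    # maximum occurred.
    if not held_speeds:
        raise ValueError("no stage was held for >= 60 s")
    peak_speed = float(stage_speeds[int(np.argmax(windows))])
    at_or_below = [s for s in held_speeds if s <= peak_speed]
    return vo2max, max(at_or_below) if at_or_below else min(held_speeds)


def percent_vo2max(set_values: np.ndarray, vo2max: float) -> float:
    """Mean of the 5-s samples over a set window, as % of VO2max."""
    if vo2max <= 0:
        raise ValueError("vo2max must be positive")
    vals = np.asarray(set_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no samples in the set window")
    return 100.0 * float(vals.mean()) / vo2max


def jump_percent_decrement(mean_height: float, pre_height: float) -> float:
    """Percent jumping-height decrement: mean/pre x 100 - 100 (negative = loss).

    ``mean_height`` is the average of the two trials at the timepoint.
    """
    if pre_height <= 0:
        raise ValueError("pre-test height must be positive")
    return mean_height / pre_height * 100.0 - 100.0


def delta_lactate(post: float, pre: float) -> float:
    """Blood-lactate accumulation (mmol/L): post-set minus post-warm-up."""
    if post < 0 or pre < 0:
        raise ValueError("lactate concentrations must be non-negative")
    return post - pre
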