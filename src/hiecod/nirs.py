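"""Near-infrared spectroscopy (NIRS) muscle-oxygenation indices.

The oxygenation index is Hbdiff = (HbO2 - HHb) / 2, reported as a change from
a 30-s pre-exercise baseline in micromolar units; more negative values mean
greater deoxygenation.  Concentrations are accepted already in uM (the
continuous-wave device emits concentrations using a fixed differential
pathlength factor, 3.83, carried as metadata); no Beer-Lambert reconstruction
is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NirsTrace", "compute_hbdiff", "delta_from_baseline", "set_summary"]

DEFAULT_DPF = 3.83


@dataclass
class NirsTrace:
    """HbO2/HHb time series from one probe site.

    ``t0`` is the time of the first sample relative to the protocol origin;
    ``baseline_window`` is a (start, end) interval in the same time base,
    expected to cover at least 30 s of pre-exercise rest.
    """

    sampling_rate: float
    site: str
    hbo2: np.ndarray
    hhb: np.ndarray
    t0: float = 0.0
    dpf: float = DEFAULT_DPF
    baseline_window: tuple[float, float] = (-30.0, 0.0)

    def __post_init__(self) -> None:
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.hbo2.shape != self.hhb.shape or self.hbo2.ndim != 1:
            raise ValueError("hbo2 and hhb must be 1-D series of equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.hbo2.size) / self.sampling_rate

    def slice_window(self, series: np.ndarray, window: tuple[float, float]) -> np.ndarray:
        """Samples of ``series`` inside the half-open time window."""
        start = int(np.ceil((window[0] - self.t0) * self.sampling_rate - 1e-9))
        end = int(np.ceil((window[1] - self.t0) * self.sampling_rate - 1e-9))
        start = max(start, 0)
        end = min(end, series.size)
        if end <= start:
            raise ValueError(f"window {window} is empty or outside the trace")
        return series[start:end]


def compute_hbdiff(hbo2: np.ndarray, hhb: np.ndarray) -> np.ndarray:
    """Oxygenation index Hbdiff = (HbO2 - HHb) / 2, pointwise in uM."""
    hbo2 = np.asarray(hbo2, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if hbo2.shape != hhb.shape:
        raise ValueError("HbO2 and HHb series must have equal length")
    return (hbo2 - hhb) / 2.0


def delta_from_baseline(trace: NirsTrace, series: np.ndarray) -> np.ndarray:
    """Series expressed as change from the mean over the trace's baseline window."""
    series = np.asarray(series, dtype=float)
    if series.shape != trace.hbo2.shape:
        raise ValueError("series must share the trace's time base")
    baseline = trace.slice_window(series, trace.baseline_window)
    return series - baseline.mean()


def set_summary(trace: NirsTrace, series: np.ndarray,
                window: tuple[float, float]) -> tuple[float, float]:
    """(mean, plateau) of a series over a set window, in uM.

    The plateau is the mean over the second half of the window, where the
    deoxygenation response has settled after its rapid initial drop.
    """
    full = trace.slice_window(np.asarray(series, dtype=float), window)
    midpoint = (window[0] + window[1]) / 2.0
    second_half = trace.slice_window(np.asarray(series, dtype=float), (midpoint, window[1]))
    return float(full.mean()), float(second_half.mean())
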