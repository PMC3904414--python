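"""Magnitude-based inference (MBI).

Paired outcomes are analysed on the natural-log scale (percent effects are
multiplicative), an effect is judged against the smallest worthwhile change
(SWC = 0.2 x the between-subject SD, Cohen's small-effect convention), and
the chances that the true difference is greater than, similar to, or lower
than the SWC band are computed from the t distribution with n - 1 degrees of
freedom and standard error SD/sqrt(n).  Chances map to the qualitative
probability scale (possible, likely, very likely, ...) and an effect is
"unclear" when both directions have more than a 5% chance.

Signed outcomes that can be non-positive (Hbdiff changes, jump-height
decrements) bypass the log-transform and are analysed on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import MbiConfig

__all__ = [
    "ComparisonResult",
    "log_transform",
    "smallest_worthwhile_change",
    "chance_triple",
    "qualify_probability",
    "classify_comparison",
    "compare_paired",
]

#: Qualitative probability scale: (upper bound, descriptor); bins are
#: left-open/right-closed above the first so they partition [0, 1] exactly.
PROBABILITY_SCALE = (
    (0.01, "almost certainly not"),
    (0.05, "very unlikely"),
    (0.25, "unlikely"),
    (0.75, "possible"),
    (0.95, "likely"),
    (0.99, "very likely"),
    (1.00, "almost certain"),
)

_ADVERB = {
    "almost certainly not": "almost certainly not",
    "very unlikely": "very unlikely",
    "unlikely": "unlikely",
    "possible": "possibly",
    "likely": "likely",
    "very likely": "very likely",
    "almost certain": "almost certainly",
}


@dataclass(frozen=True)
class ComparisonResult:
    """MBI output for one paired comparison."""

    outcome: str
    mean_diff_pct: float
    sd_diff_pct: float
    p_greater: float
    p_similar: float
    p_lower: float
    label: str
    n: int
    swc: float
    log_scale: bool

    @property
    def chances(self) -> tuple[float, float, float]:
        return (self.p_greater, self.p_similar, self.p_lower)

    def format(self) -> str:
        """Report-style one-liner, e.g. ``+9.7 +/- 10.4%, 57/42/0 -- possibly higher``."""
        unit = "%" if self.log_scale else ""
        triple = "/".join(str(int(round(100 * p))) for p in self.chances)
        return (f"{self.mean_diff_pct:+.1f} ± {self.sd_diff_pct:.1f}{unit}, "
                f"{triple} — {self.label}")


def log_transform(values: np.ndarray) -> np.ndarray:
    """Natural log, elementwise; inputs must be strictly positive.

    Differences of logs back-transform to percent via ``100 * (exp(d) - 1)``.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("log-transform requires strictly positive values")
    return np.log(values)


def smallest_worthwhile_change(between_subject_sd: float, multiplier: float = 0.2) -> float:
    """SWC = multiplier x between-subject SD (same scale as the SD)."""
    if between_subject_sd < 0:
        raise ValueError("between-subject SD must be >= 0")
    return multiplier * between_subject_sd


def chance_triple(mean_diff: float, sd_diff: float, n: int, swc: float
                  ) -> tuple[float, float, float]:
    """(p_greater, p_similar, p_lower) for a paired mean difference.

    With SE = sd_diff / sqrt(n) and df = n - 1, the true difference is
    modelled as mean_diff + SE * T_df; p_greater is the probability it
    exceeds +swc and p_lower the probability it falls below -swc.  A
    degenerate SE of 0 yields indicator probabilities.
    """
    if n < 2:
        raise ValueError("chance_triple requires n >= 2")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    if swc < 0:
        raise ValueError("swc must be >= 0")
    se = sd_diff / np.sqrt(n)
    with np.errstate(over="ignore", divide="ignore"):
        degenerate = se == 0 or not np.isfinite((swc + abs(mean_diff)) / se)
    if degenerate:
        if mean_diff > swc:
            return (1.0, 0.0, 0.0)
        if mean_diff < -swc:
            return (0.0, 0.0, 1.0)
        return (0.0, 1.0, 0.0)
    df = n - 1
    p_greater = float(stats.t.sf((swc - mean_diff) / se, df))
    p_lower = float(stats.t.sf((swc + mean_diff) / se, df))
    p_similar = 1.0 - p_greater - p_lower
    return (p_greater, max(p_similar, 0.0), p_lower)


def qualify_probability(p: float) -> str:
    """Qualitative descriptor of a probability on the published scale."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    for upper, label in PROBABILITY_SCALE:
        if p <= upper:
            return label
    return PROBABILITY_SCALE[-1][1]  # pragma: no cover - p == 1 handled above


def classify_comparison(triple: tuple[float, float, float],
                        direction_labels: tuple[str, str, str] = ("higher", "similar", "lower"),
                        unclear_threshold: float = 0.05) -> str:
    """Qualitative label for a chance triple.

    "unclear" when both directions exceed the unclear threshold; otherwise
    the descriptor of the dominant component composed with its direction
    word (e.g. ``(0.57, 0.42, 0.00)`` -> "possibly higher").
    """
    p_greater, p_similar, p_lower = triple
    for p in triple:
        if not (0.0 <= p <= 1.0 + 1e-9):
            raise ValueError("chance triple components must lie in [0, 1]")
    if p_greater > unclear_threshold and p_lower > unclear_threshold:
        return "unclear"
    idx = int(np.argmax(triple))
    descriptor = qualify_probability(min(triple[idx], 1.0))
    return f"{_ADVERB[descriptor]} {direction_labels[idx]}"


def compare_paired(values_a: np.ndarray, values_b: np.ndarray, outcome: str = "",
                   config: MbiConfig | None = None, log_scale: bool = True,
                   reference_values: np.ndarray | None = None) -> ComparisonResult:
    """MBI comparison of paired observations (b vs a).

    ``values_a`` is the reference condition (or timepoint).  On the log scale
    the reported mean/SD are back-transformed to percent; on the raw scale
    (signed outcomes) they stay in the outcome's units.  The SWC comes from
    the between-subject SD of ``reference_values`` (default: ``values_a``)
    on the analysis scale.
    """
    config = config or MbiConfig()
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired comparison requires n >= 2")
    ref = a if reference_values is None else np.asarray(reference_values, dtype=float)

    if log_scale:
        diffs = log_transform(b) - log_transform(a)
        ref_scale = log_transform(ref)
    else:
        diffs = b - a
        ref_scale = ref

    mean_d = float(diffs.mean())
    sd_d = float(diffs.std(ddof=1))
    between_sd = float(ref_scale.std(ddof=1))
    swc = smallest_worthwhile_change(between_sd, config.swc_multiplier)
    triple = chance_triple(mean_d, sd_d, n, swc)
    label = classify_comparison(triple, unclear_threshold=config.unclear_threshold)

    if log_scale:
        mean_pct = 100.0 * (np.exp(mean_d) - 1.0)
        sd_pct = 100.0 * (np.exp(sd_d) - 1.0)
    else:
        mean_pct, sd_pct = mean_d, sd_d

    return ComparisonResult(
        outcome=outcome, mean_diff_pct=float(mean_pct), sd_diff_pct=float(sd_pct),
        p_greater=triple[0], p_similar=triple[1], p_lower=triple[2],
        label=label, n=n, swc=swc, log_scale=log_scale,
    )
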