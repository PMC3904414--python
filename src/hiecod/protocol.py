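"""Study-design computations for the high-intensity intermittent effort (HIE) protocol.

The protocol is 2 sets of 10 brief (4-s) runs departing every 16 s, separated
by 2 min 20 s of rest, performed once in a straight line over 22 m and once
with two 90-degree changes of direction (COD).  Because turning costs time,
the COD run distance is shortened per subject by the ratio of their
straight-line to COD 22-m sprint times, so that both conditions prescribe the
same running *time* at each subject's relative maximal effort.

Time origin: t = 0 at the onset of the first run of set 1; all windows are
half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HieSchedule",
    "adjust_cod_distance",
    "maximal_sprint_speed",
    "relative_intensity",
    "build_hie_schedule",
    "schedule_table",
]

#: Base straight-line run distance, metres.
BASE_DISTANCE_M = 22.0


@dataclass(frozen=True)
class HieSchedule:
    """Timing and distance of one subject's HIE session.

    Run k of set s (both 0-based) starts at
    ``s * (n_runs_per_set * depart_interval + inter_set_rest) + k * depart_interval``.
    """

    run_distance_m: float
    n_runs_per_set: int = 10
    run_duration_s: float = 4.0
    depart_interval_s: float = 16.0
    n_sets: int = 2
    inter_set_rest_s: float = 140.0
    recovery_speed_kmh: float = 6.0

    def __post_init__(self) -> None:
        if self.depart_interval_s <= self.run_duration_s:
            raise ValueError("depart interval must exceed run duration")
        for name in ("run_distance_m", "n_runs_per_set", "run_duration_s",
                     "depart_interval_s", "n_sets", "inter_set_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def set_offset(self, set_index: int) -> float:
        """Start time of the first run of ``set_index`` (0-based)."""
        period = self.n_runs_per_set * self.depart_interval_s + self.inter_set_rest_s
        return set_index * period

    def run_start(self, set_index: int, run_index: int) -> float:
        return self.set_offset(set_index) + run_index * self.depart_interval_s

    def run_windows(self) -> list[tuple[int, int, float, float]]:
        """All (set, run, start, end) run windows, ordered and disjoint."""
        out = []
        for s in range(self.n_sets):
            for k in range(self.n_runs_per_set):
                start = self.run_start(s, k)
                out.append((s, k, start, start + self.run_duration_s))
        return out

    def set_window(self, set_index: int) -> tuple[float, float]:
        """Whole-set window: first run onset to end of the last recovery."""
        start = self.set_offset(set_index)
        return start, start + self.n_runs_per_set * self.depart_interval_s

    @property
    def total_duration_s(self) -> float:
        return self.set_window(self.n_sets - 1)[1]


def adjust_cod_distance(t_sl: float, t_cod: float, base_distance: float = BASE_DISTANCE_M) -> float:
    """Individually adjusted COD run distance (m).

    ``t_sl`` and ``t_cod`` are the subject's 22-m sprint times without and
    with the two 90-degree turns.  The adjusted distance is
    ``t_sl * base_distance / t_cod``: the distance the subject covers while
    turning in the time a straight sprint would take over ``base_distance``.
    Scale-invariant in the time unit.
    """
    if t_sl <= 0 or t_cod <= 0:
        raise ValueError("sprint times must be positive")
    if base_distance <= 0:
        raise ValueError("base distance must be positive")
    return t_sl * base_distance / t_cod


def maximal_sprint_speed(split_times_10m: Sequence[float]) -> float:
    """Maximal sprint speed (m/s): 10 m over the fastest 10-m split.

    ``split_times_10m`` holds segment times from one or both 40-m sprints;
    the global best segment across every supplied sprint governs.
    """
    times = list(split_times_10m)
    if not times:
        raise ValueError("at least one 10-m split time is required")
    if min(times) <= 0:
        raise ValueError("split times must be positive")
    return 10.0 / min(times)


def relative_intensity(distance_m: float, duration_s: float, mss_ms: float,
                       vvo2max_kmh: float) -> tuple[float, float]:
    """Average run speed as (%MSS, %vVO2max).

    MSS is in m/s, vVO2max in km/h; the average speed ``distance/duration``
    is converted as needed (1 m/s = 3.6 km/h).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if distance_m <= 0 or mss_ms <= 0 or vvo2max_kmh <= 0:
        raise ValueError("distance, MSS and vVO2max must be positive")
    speed_ms = distance_m / duration_s
    pct_mss = 100.0 * speed_ms / mss_ms
    pct_vvo2max = 100.0 * (speed_ms * 3.6) / vvo2max_kmh
    return pct_mss, pct_vvo2max


def build_hie_schedule(condition: str, profiles: Iterable) -> dict[str, HieSchedule]:
    """Per-subject HIE schedules for a condition.

    Straight-line sessions use the 22-m base distance for everyone; COD
    sessions use each subject's adjusted distance.
    """
    if condition not in ("SL", "COD"):
        raise ValueError(f"unknown condition {condition!r}")
    out: dict[str, HieSchedule] = {}
    for p in profiles:
        if condition == "SL":
            dist = BASE_DISTANCE_M
        else:
            dist = adjust_cod_distance(p.t_sprint_sl, p.t_sprint_cod)
        out[p.subject_id] = HieSchedule(run_distance_m=dist)
    return out


def schedule_table(schedules: dict[str, HieSchedule], condition: str) -> pd.DataFrame:
    """Flatten schedules into a table (one row per run window)."""
    rows = []
    for subject_id, sched in schedules.items():
        for s, k, start, end in sched.run_windows():
            rows.append({
                "subject_id": subject_id,
                "condition": condition,
                "set": f"set{s + 1}",
                "run_index": k,
                "start_s": start,
                "end_s": end,
                "distance_m": sched.run_distance_m,
            })
    return pd.DataFrame(rows)
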