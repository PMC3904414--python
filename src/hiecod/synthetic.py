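"""Seeded synthetic cohorts and signals with the statistical structure the
analysis assumes.

The generator emulates a crossover study of eleven team-sport players who
performed two sets of ten 4-s high-intensity runs (departing every 16 s,
2 min 20 s between sets) in a straight line over 22 m and with two
90-degree changes of direction over an individually adjusted distance
(straight/COD sprint-time ratio 0.75 +/- 0.02).  It produces:

* per-subject anthropometric/capacity profiles,
* surface-EMG traces (1000 Hz, 8 muscles): each stride is a raised-cosine
  RMS envelope riding on a deterministic multi-tone carrier inside the
  20-450 Hz analysis band, plus additive white noise,
* NIRS HbO2/HHb traces (10 Hz, 2 sites) whose Hbdiff drops
  mono-exponentially to a plateau within each set and recovers between sets,
* breath-by-breath oxygen uptake with a configurable set-2 elevation,
* scalar outcomes (lactate, RPE, jump heights) with multiplicative
  condition/set effects on the natural-log scale.

Ground truth (stride onsets/offsets, per-set amplitudes, plateau values,
per-subject effect draws) is always emitted alongside the signals so every
downstream detector can be scored exactly.  All randomness flows from one
root seed through independent, order-independent substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cardio import BreathTrace
from .config import CHANNELS, CONDITIONS, NIRS_SITES, GeneratorConfig
from .emg import EmgRecording
from .nirs import NirsTrace
from .protocol import BASE_DISTANCE_M, HieSchedule, adjust_cod_distance

__all__ = [
    "SubjectProfile",
    "TrialTruth",
    "TrialSignals",
    "generate_cohort",
    "generate_trial_signals",
    "generate_sprint_recording",
    "generate_breath_trace",
    "generate_incremental_test",
    "generate_outcomes",
    "cohort_table",
]

# Substream purpose codes (order-independent seeding: every stream is keyed
# by (root seed, subject index, purpose, condition)).
_P_PROFILE, _P_EMG, _P_NIRS, _P_BREATH, _P_SPRINT, _P_OUTCOME, _P_INCR = range(7)
_COND_CODE = {"SL": 0, "COD": 1}

#: Stride-envelope shape parameters: raised-cosine bumps of 200 ms every
#: 280 ms during runs (240 ms during the maximal sprint), first onset 60 ms
#: after the run start.
RUN_STRIDE_OFFSET_S = 0.06
EMG_T0_S = -36.0
EMG_TAIL_S = 6.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _log_sd(pct: float) -> float:
    return math.log1p(pct / 100.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject anthropometrics and capacities."""

    subject_id: str
    index: int
    mss: float            # maximal sprint speed, m/s
    vvo2max: float        # km/h, on the 0.5 km/h stage grid
    vo2max: float         # mL/min/kg
    t_sprint_sl: float    # 22-m straight sprint time, s
    t_sprint_cod: float   # 22-m sprint with two 90-degree turns, s
    jump_cmj_baseline: float  # cm
    jump_dj_baseline: float   # cm

    def __post_init__(self) -> None:
        if not (self.t_sprint_cod > self.t_sprint_sl > 0):
            raise ValueError("sprint times must satisfy t_cod > t_sl > 0")
        if min(self.mss, self.vvo2max, self.vo2max,
               self.jump_cmj_baseline, self.jump_dj_baseline) <= 0:
            raise ValueError("capacities and jump heights must be positive")

    @property
    def sprint_ratio(self) -> float:
        return self.t_sprint_sl / self.t_sprint_cod

    @property
    def cod_distance(self) -> float:
        return adjust_cod_distance(self.t_sprint_sl, self.t_sprint_cod)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise RuntimeError("truncated normal rejection failed; check bounds")


def generate_cohort(config: GeneratorConfig) -> list[SubjectProfile]:
    """Deterministic cohort of :class:`SubjectProfile` for the configured seed."""
    config.validate()
    cs = config.cohort
    profiles = []
    for i in range(config.n_subjects):
        rng = _rng(config.seed, i, _P_PROFILE)
        mss = _truncated_normal(rng, cs.mss_mean_ms, cs.mss_sd_ms, 3.0, 12.0)
        vvo2max = _truncated_normal(rng, cs.vvo2max_mean_kmh, cs.vvo2max_sd_kmh, 10.0, 24.0)
        vvo2max = round(vvo2max * 2.0) / 2.0  # incremental-test stage grid
        vo2max = _truncated_normal(rng, cs.vo2max_mean, cs.vo2max_sd, 30.0, 90.0)
        t_sl = BASE_DISTANCE_M / (cs.sprint22_rel_speed * mss)
        ratio = _truncated_normal(rng, config.sl_cod_ratio_mean,
                                  config.sl_cod_ratio_sd, 0.0, 1.0)
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            index=i,
            mss=mss,
            vvo2max=vvo2max,
            vo2max=vo2max,
            t_sprint_sl=t_sl,
            t_sprint_cod=t_sl / ratio,
            jump_cmj_baseline=_truncated_normal(rng, cs.cmj_mean_cm, cs.cmj_sd_cm, 10.0, 80.0),
            jump_dj_baseline=_truncated_normal(rng, cs.dj_mean_cm, cs.dj_sd_cm, 8.0, 80.0),
        ))
    return profiles


def cohort_table(cohort: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        rows.append({
            "subject_id": p.subject_id, "mss_ms": p.mss, "vvo2max_kmh": p.vvo2max,
            "vo2max_mlminkg": p.vo2max, "t_sprint_sl_s": p.t_sprint_sl,
            "t_sprint_cod_s": p.t_sprint_cod, "sprint_ratio": p.sprint_ratio,
            "cod_distance_m": p.cod_distance,
            "cmj_baseline_cm": p.jump_cmj_baseline, "dj_baseline_cm": p.jump_dj_baseline,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EMG


def _raised_cosine(env: np.ndarray, t0: float, fs: float, onset: float,
                   duration: float, amplitude: float) -> None:
    i0 = int(round((onset - t0) * fs))
    n = int(round(duration * fs))
    i0 = max(i0, 0)
    i1 = min(i0 + n, env.size)
    tau = np.arange(i1 - i0) / fs
    env[i0:i1] += amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / duration))


def _carrier(rng: np.random.Generator, n: int, fs: float,
             freqs: tuple[float, ...]) -> np.ndarray:
    """Unit-RMS deterministic multi-tone carrier with random phases."""
    t = np.arange(n) / fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    out = np.zeros(n)
    for f, ph in zip(freqs, phases):
        out += np.sin(2.0 * np.pi * f * t + ph)
    return out * math.sqrt(2.0 / len(freqs))


@dataclass
class TrialTruth:
    """Generator ground truth for one subject x condition trial."""

    strides: pd.DataFrame        # channel, set, run, onset_s, offset_s, amplitude_uv
    set_amplitudes: pd.DataFrame  # channel, set, amplitude_uv, normalized_pct
    nirs_plateau: pd.DataFrame   # site, set, plateau_um
    vo2: pd.DataFrame            # set, pct_vo2max, vo2_mlminkg


@dataclass
class TrialSignals:
    subject_id: str
    condition: str
    schedule: HieSchedule
    emg: EmgRecording
    nirs: dict[str, NirsTrace]
    breath: BreathTrace
    truth: TrialTruth


def _trial_schedule(profile: SubjectProfile, condition: str) -> HieSchedule:
    dist = BASE_DISTANCE_M if condition == "SL" else profile.cod_distance
    return HieSchedule(run_distance_m=dist)


def _generate_emg(profile: SubjectProfile, condition: str, config: GeneratorConfig,
                  schedule: HieSchedule) -> tuple[EmgRecording, pd.DataFrame, pd.DataFrame]:
    spec = config.emg
    fs = spec.sampling_rate_hz
    t0 = EMG_T0_S
    t_end = schedule.total_duration_s + EMG_TAIL_S
    n = int(round((t_end - t0) * fs))
    rng = _rng(config.seed, profile.index, _P_EMG, _COND_CODE[condition])
    # carrier phases model electrode/muscle geometry: fixed per subject and
    # channel, independent of the condition, so that zero-effect, zero-noise
    # configurations yield identical traces in both conditions
    carrier_rng = _rng(config.seed, profile.index, _P_EMG, 2)

    data = np.empty((len(CHANNELS), n))
    stride_rows = []
    amp_rows = []
    run_windows = schedule.run_windows()
    for ci, ch in enumerate(CHANNELS):
        env = np.zeros(n)
        amp_by_set = {}
        for s in range(schedule.n_sets):
            set_name = f"set{s + 1}"
            dec = spec.decrement_pct[condition][set_name].get(ch, 0.0)
            if spec.decrement_sd_pct > 0:
                dec += rng.normal(0.0, spec.decrement_sd_pct)
            dec = max(dec, -80.0)
            amp = spec.amplitude_uv[ch] * spec.hie_rel_amplitude * (1.0 + dec / 100.0)
            amp_by_set[set_name] = amp
            amp_rows.append({
                "channel": ch, "set": set_name, "amplitude_uv": amp,
                "normalized_pct": 100.0 * amp / spec.amplitude_uv[ch],
            })
        for s, k, start, end in run_windows:
            set_name = f"set{s + 1}"
            amp = amp_by_set[set_name]
            onset = start + RUN_STRIDE_OFFSET_S
            while onset + spec.burst_duration_s <= end - 0.05:
                _raised_cosine(env, t0, fs, onset, spec.burst_duration_s, amp)
                stride_rows.append({
                    "channel": ch, "set": set_name, "run": k,
                    "onset_s": onset, "offset_s": onset + spec.burst_duration_s,
                    "amplitude_uv": amp,
                })
                onset += spec.stride_interval_s
        for s, k, start, end in run_windows:
            # low-amplitude jog strides during the 16-s active recovery,
            # stopping 3.4 s before the next departure (ready position)
            next_start = start + schedule.depart_interval_s
            jog_on = end + 0.5
            while jog_on + spec.burst_duration_s <= next_start - 3.4 and \
                    jog_on + spec.burst_duration_s <= schedule.set_window(s)[1]:
                _raised_cosine(env, t0, fs, jog_on, spec.burst_duration_s,
                               spec.jog_amplitude_uv)
                jog_on += 0.5
        carrier = _carrier(carrier_rng, n, fs, spec.carrier_freqs_hz)
        noise = rng.normal(0.0, spec.noise_sd_uv, size=n) if spec.noise_sd_uv > 0 else 0.0
        data[ci] = env * carrier + noise

    rec = EmgRecording(sampling_rate=fs, channel_names=CHANNELS, data=data, t0=t0)
    return rec, pd.DataFrame(stride_rows), pd.DataFrame(amp_rows)


def generate_sprint_recording(profile: SubjectProfile, config: GeneratorConfig
                              ) -> tuple[EmgRecording, pd.DataFrame]:
    """EMG of the subject's fastest 22-m straight sprint (for normalization).

    The sprint starts at t = 0 of its own time base after a 3-s quiet ready
    period; stride amplitudes equal the per-muscle maximal-run amplitude.
    Returns the recording and a stride ground-truth table.
    """
    spec = config.emg
    fs = spec.sampling_rate_hz
    duration = profile.t_sprint_sl
    t0, t_end = -3.5, duration + 1.0
    n = int(round((t_end - t0) * fs))
    rng = _rng(config.seed, profile.index, _P_SPRINT)

    data = np.empty((len(CHANNELS), n))
    rows = []
    for ci, ch in enumerate(CHANNELS):
        env = np.zeros(n)
        amp = spec.amplitude_uv[ch]
        onset = 0.05
        while onset + spec.burst_duration_s <= duration - 0.05:
            _raised_cosine(env, t0, fs, onset, spec.burst_duration_s, amp)
            rows.append({"channel": ch, "onset_s": onset,
                         "offset_s": onset + spec.burst_duration_s,
                         "amplitude_uv": amp})
            onset += spec.sprint_stride_interval_s
        carrier = _carrier(rng, n, fs, spec.carrier_freqs_hz)
        noise = rng.normal(0.0, spec.noise_sd_uv, size=n) if spec.noise_sd_uv > 0 else 0.0
        data[ci] = env * carrier + noise

    rec = EmgRecording(sampling_rate=fs, channel_names=CHANNELS, data=data, t0=t0)
    return rec, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIRS


def _hbdiff_curve(times: np.ndarray, schedule: HieSchedule, plateau: float,
                  tau: float) -> np.ndarray:
    """Piecewise mono-exponential Hbdiff change: drop to plateau within each
    set, recovery toward baseline between/after sets, continuous throughout."""
    d = np.zeros_like(times)
    value = 0.0  # running value at segment boundaries
    segments = []
    for s in range(schedule.n_sets):
        start, end = schedule.set_window(s)
        segments.append((start, end, plateau))
        nxt = schedule.set_window(s + 1)[0] if s + 1 < schedule.n_sets else times[-1] + 1.0
        segments.append((end, nxt, 0.0))
    for start, end, target in segments:
        mask = (times >= start) & (times < end)
        d[mask] = target + (value - target) * np.exp(-(times[mask] - start) / tau)
        value = target + (value - target) * math.exp(-(end - start) / tau)
    return d


def _generate_nirs(profile: SubjectProfile, condition: str, config: GeneratorConfig,
                   schedule: HieSchedule) -> tuple[dict[str, NirsTrace], pd.DataFrame]:
    spec = config.nirs
    fs = spec.sampling_rate_hz
    t0 = -(spec.baseline_s + 6.0)
    t_end = schedule.total_duration_s + EMG_TAIL_S
    times = t0 + np.arange(int(round((t_end - t0) * fs))) / fs
    rng = _rng(config.seed, profile.index, _P_NIRS, _COND_CODE[condition])

    hbo2_base, hhb_base = 60.0, 40.0  # resting concentrations, uM
    traces: dict[str, NirsTrace] = {}
    rows = []
    for site in NIRS_SITES:
        plateau = spec.plateau_um[site] * math.exp(
            rng.normal(0.0, _log_sd(spec.between_sd_pct)))
        d = _hbdiff_curve(times, schedule, plateau, spec.tau_s)
        noise_o = rng.normal(0.0, spec.noise_sd_um, size=times.size)
        noise_h = rng.normal(0.0, spec.noise_sd_um, size=times.size)
        traces[site] = NirsTrace(
            sampling_rate=fs, site=site,
            hbo2=hbo2_base + d + noise_o,
            hhb=hhb_base - d + noise_h,
            t0=t0, dpf=spec.dpf,
            baseline_window=(-spec.baseline_s, 0.0),
        )
        for s in range(schedule.n_sets):
            rows.append({"site": site, "set": f"set{s + 1}", "plateau_um": plateau})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Breath-by-breath oxygen uptake


def _exp_segment_mean_factor(length: float, tau: float) -> float:
    """Mean of exp(-t/tau) over [0, length]."""
    return tau / length * (1.0 - math.exp(-length / tau))


def generate_breath_trace(profile: SubjectProfile, condition: str,
                          config: GeneratorConfig, schedule: HieSchedule | None = None
                          ) -> tuple[BreathTrace, pd.DataFrame]:
    """Breath-by-breath VO2 (mL/min/kg) for one HIE trial, plus truth.

    The underlying curve rises first-order within each set and decays during
    rest; the set plateaus are chosen analytically so that the *mean over the
    whole set window* equals the per-subject target, which is what the
    analysis recovers.  Truth rows give the target set means (% VO2max).
    """
    schedule = schedule or _trial_schedule(profile, condition)
    spec = config.breath
    rng = _rng(config.seed, profile.index, _P_BREATH, _COND_CODE[condition])

    # a subject's relative aerobic engagement is a trait, drawn once per
    # subject from a condition-independent stream
    subj_rng = _rng(config.seed, profile.index, _P_BREATH, 3)
    subj_factor = math.exp(subj_rng.normal(0.0, _log_sd(spec.between_sd_pct)))
    set1_pct = spec.set1_pct_vo2max[condition] * subj_factor
    eff = math.exp(rng.normal(_log_sd(spec.set_effect_pct[condition]),
                              _log_sd(spec.set_effect_sd_pct[condition])))
    set2_pct = set1_pct * eff
    targets = [set1_pct, set2_pct]

    base = spec.baseline_pct_vo2max / 100.0 * profile.vo2max
    means = [p / 100.0 * profile.vo2max for p in targets]

    # breath timestamps are a property of the subject's breathing pattern,
    # drawn from a condition-independent stream
    times_rng = _rng(config.seed, profile.index, _P_BREATH, 2)
    t0 = -(config.nirs.baseline_s + 6.0)
    t_end = schedule.total_duration_s + EMG_TAIL_S
    times = []
    t = t0
    while t < t_end:
        times.append(t)
        t += max(0.8, times_rng.normal(spec.mean_interval_s, spec.interval_jitter_s))
    times = np.asarray(times)

    # piecewise curve with set plateaus solved so set-window means hit targets
    v = np.full(times.size, base)
    value = base
    segments = []
    for s in range(schedule.n_sets):
        start, end = schedule.set_window(s)
        h = _exp_segment_mean_factor(end - start, spec.tau_on_s)
        plateau = (means[s] - value * h) / (1.0 - h)
        segments.append((start, end, plateau, spec.tau_on_s))
        nxt = schedule.set_window(s + 1)[0] if s + 1 < schedule.n_sets else t_end + 1.0
        value_end = plateau + (value - plateau) * math.exp(-(end - start) / spec.tau_on_s)
        segments.append((end, nxt, base, spec.tau_off_s))
        value = base + (value_end - base) * math.exp(-(nxt - end) / spec.tau_off_s)
    value = base
    for start, end, target, tau in segments:
        mask = (times >= start) & (times < end)
        v[mask] = target + (value - target) * np.exp(-(times[mask] - start) / tau)
        value = target + (value - target) * math.exp(-(end - start) / tau)

    if spec.breath_noise_pct > 0:
        v = v * (1.0 + rng.normal(0.0, spec.breath_noise_pct / 100.0, size=v.size))
    v = np.maximum(v, 0.1)

    truth = pd.DataFrame({
        "set": [f"set{s + 1}" for s in range(schedule.n_sets)],
        "pct_vo2max": targets,
        "vo2_mlminkg": means,
    })
    return BreathTrace(times=times, values=v), truth


def generate_incremental_test(profile: SubjectProfile, config: GeneratorConfig
                              ) -> tuple[BreathTrace, np.ndarray, float]:
    """Breath-by-breath incremental running test (stages of 60 s, +0.5 km/h
    from 8 km/h; the subject completes the vVO2max stage and 40 s of the next).

    Returns the trace, a function-of-time stage-speed array is left to the
    caller via the returned stage duration grid: (trace, stage_speeds_per_5s,
    test_duration_s).
    """
    spec = config.breath
    rng = _rng(config.seed, profile.index, _P_INCR)

    start_speed, step, stage_s = 8.0, 0.5, 60.0
    n_full = int(round((profile.vvo2max - start_speed) / step)) + 1
    duration = n_full * stage_s + 40.0

    b0 = 5.0  # resting intercept, mL/min/kg
    slope = (profile.vo2max - b0) / profile.vvo2max

    def stage_speed(t: float) -> float:
        return start_speed + step * min(int(t // stage_s), n_full)

    def target(t: float) -> float:
        return min(b0 + slope * stage_speed(t), profile.vo2max)

    times = []
    t = 0.0
    while t < duration:
        times.append(t)
        t += max(0.8, rng.normal(spec.mean_interval_s, spec.interval_jitter_s))
    times = np.asarray(times)

    tau = 20.0
    v = np.empty(times.size)
    value = target(0.0)
    prev_t = 0.0
    for i, tb in enumerate(times):
        tgt = target(tb)
        value = tgt + (value - tgt) * math.exp(-(tb - prev_t) / tau)
        v[i] = value
        prev_t = tb
    if spec.breath_noise_pct > 0:
        v = v * (1.0 + rng.normal(0.0, spec.breath_noise_pct / 100.0, size=v.size))

    n_bins = int(math.ceil(duration / 5.0))
    bin_times = 5.0 * np.arange(n_bins)
    speeds = np.array([stage_speed(t) for t in bin_times])
    return BreathTrace(times=times, values=v), speeds, duration


# ---------------------------------------------------------------------------
# Trial assembly and scalar outcomes


def generate_trial_signals(profile: SubjectProfile, condition: str,
                           config: GeneratorConfig) -> TrialSignals:
    """All signals plus ground truth for one subject x condition HIE session."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config.validate()
    schedule = _trial_schedule(profile, condition)
    emg_rec, strides, set_amp = _generate_emg(profile, condition, config, schedule)
    nirs_traces, nirs_truth = _generate_nirs(profile, condition, config, schedule)
    breath, vo2_truth = generate_breath_trace(profile, condition, config, schedule)
    truth = TrialTruth(strides=strides, set_amplitudes=set_amp,
                       nirs_plateau=nirs_truth, vo2=vo2_truth)
    return TrialSignals(subject_id=profile.subject_id, condition=condition,
                        schedule=schedule, emg=emg_rec, nirs=nirs_traces,
                        breath=breath, truth=truth)


def generate_outcomes(cohort: list[SubjectProfile], config: GeneratorConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scalar outcomes (lactate concentrations, RPE, jump heights) per
    subject, condition, timepoint and trial, plus per-subject effect truth.

    Effects are applied multiplicatively on the natural-log scale: for
    outcome value y of subject i, condition c, timepoint t,
    ``log y = log(baseline) + b_i + cond_i * [c == COD] + tp_i(t) + eps``.
    Jump outcomes carry two trials per timepoint; lactate rows are
    concentrations (timepoints pre/set1/set2) from which the analysis forms
    per-set accumulations.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    truth_rows = []
    for p in cohort:
        rng = _rng(config.seed, p.index, _P_OUTCOME)
        for name, spec in config.effects.items():
            baseline = spec.baseline
            if name == "cmj_height":
                baseline = p.jump_cmj_baseline
            elif name == "dj_height":
                baseline = p.jump_dj_baseline
            else:
                baseline = baseline * math.exp(rng.normal(0.0, _log_sd(spec.between_sd_pct)))
            cond_eff = rng.normal(_log_sd(spec.condition_pct), _log_sd(spec.condition_sd_pct))
            tp_eff = {}
            for tp, pct in spec.timepoint_pct.items():
                sd = spec.timepoint_sd_pct.get(tp, 0.0)
                tp_eff[tp] = rng.normal(_log_sd(pct), _log_sd(sd))
            truth_rows.append({"subject_id": p.subject_id, "outcome": name,
                               "param": "condition_effect_pct",
                               "value": 100.0 * (math.exp(cond_eff) - 1.0)})
            for tp, eff in tp_eff.items():
                truth_rows.append({"subject_id": p.subject_id, "outcome": name,
                                   "param": f"timepoint_effect_pct_{tp}",
                                   "value": 100.0 * (math.exp(eff) - 1.0)})
            n_trials = 2 if name in ("cmj_height", "dj_height") else 1
            if name == "delta_lactate":
                # post-warm-up concentration is a subject trait
                pre = config.lactate_pre_mmol * math.exp(rng.normal(0.0, _log_sd(10.0)))
            for condition in CONDITIONS:
                for tp in spec.timepoint_pct:
                    mu = math.log(baseline) + tp_eff[tp]
                    if condition == "COD":
                        mu += cond_eff
                    for trial in range(1, n_trials + 1):
                        eps = rng.normal(0.0, _log_sd(spec.within_sd_pct))
                        value = math.exp(mu + eps)
                        if name == "rpe":
                            value = min(value, 10.0)
                        if name == "delta_lactate":
                            continue  # emitted as concentrations below
                        rows.append({"subject_id": p.subject_id, "condition": condition,
                                     "timepoint": tp, "outcome": name, "trial": trial,
                                     "value": value, "units": spec.units})
                if name == "delta_lactate":
                    rows.append({"subject_id": p.subject_id, "condition": condition,
                                 "timepoint": "pre", "outcome": "lactate", "trial": 1,
                                 "value": pre, "units": "mmol/L"})
                    for tp in spec.timepoint_pct:
                        mu = math.log(baseline) + tp_eff[tp]
                        if condition == "COD":
                            mu += cond_eff
                        delta = math.exp(mu + rng.normal(0.0, _log_sd(spec.within_sd_pct)))
                        rows.append({"subject_id": p.subject_id, "condition": condition,
                                     "timepoint": tp, "outcome": "lactate", "trial": 1,
                                     "value": pre + delta, "units": "mmol/L"})
    outcomes = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return outcomes, truth
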