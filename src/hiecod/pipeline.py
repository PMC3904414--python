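"""End-to-end orchestration: generate -> process -> infer -> report.

Each stage is a library function operating on in-memory objects; the CLI
wraps them with file I/O.  ``run_study`` executes the whole chain for a
configuration and writes every derived table plus a human-readable summary
and a run manifest.  Signals are processed trial by trial as they are
generated, so the default study (11 subjects x 2 conditions of 1000-Hz,
8-channel EMG) never holds more than one trial in memory.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cardio import (determine_vo2max_vvo2max, jump_percent_decrement,
                     delta_lactate, percent_vo2max, resample_breaths)
from .config import CHANNELS, CONDITIONS, GeneratorConfig, MbiConfig
from .emg import (InsufficientStridesError, bandpass, detect_bursts, moving_rms,
                  normalize_amplitude, select_strides, sprint_reference,
                  summarize_set)
from .io import write_table
from .mbi import ComparisonResult, compare_paired
from .nirs import compute_hbdiff, delta_from_baseline, set_summary
from .protocol import relative_intensity, schedule_table, build_hie_schedule
from .synthetic import (SubjectProfile, TrialSignals, cohort_table,
                        generate_cohort, generate_incremental_test,
                        generate_outcomes, generate_sprint_recording,
                        generate_trial_signals)

logger = logging.getLogger("hiecod")

#: Outcomes that can be non-positive are analysed on the raw scale.
RAW_SCALE_OUTCOMES = {"hbdiff_vl", "hbdiff_bf", "cmj_dec", "dj_dec"}

NIRS_OUTCOME = {"vastus_lateralis": "hbdiff_vl", "biceps_femoris": "hbdiff_bf"}


@dataclass
class RunManifest:
    """Record of one pipeline execution, written even on partial failure."""

    seed: int
    out_dir: str
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, status: str, **counts) -> None:
        self.stages.append({"stage": stage, "status": status, **counts})
        logger.info("stage %-10s %s %s", stage, status,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    def write(self, path: Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "out_dir": self.out_dir,
                       "version": self.version, "stages": self.stages}, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Trial-level processing


def emg_reference(profile: SubjectProfile, config: GeneratorConfig) -> dict[str, float]:
    """Per-muscle normalization reference from the fastest 22-m sprint."""
    rec, _ = generate_sprint_recording(profile, config)
    return emg_reference_from_recording(rec, sprint_window=(0.0, profile.t_sprint_sl),
                                        quiet_window=(-3.2, -0.2))


def emg_reference_from_recording(rec, sprint_window: tuple[float, float],
                                 quiet_window: tuple[float, float]) -> dict[str, float]:
    filtered = bandpass(rec)
    bursts_by_channel = {}
    q0, q1 = filtered.index_of(quiet_window[0]), filtered.index_of(quiet_window[1])
    w0, w1 = filtered.index_of(sprint_window[0]), filtered.index_of(sprint_window[1])
    for ch in filtered.channel_names:
        raw = filtered.channel(ch)
        env = moving_rms(raw, filtered.sampling_rate)
        bursts = detect_bursts(env[w0:w1], filtered.sampling_rate, raw[q0:q1],
                               t0=sprint_window[0], channel=ch)
        bursts_by_channel[ch] = bursts
    return sprint_reference(bursts_by_channel)


def process_emg_trial(signals: TrialSignals, refs: dict[str, float]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Burst table and per-muscle, per-set normalized amplitude summaries."""
    filtered = bandpass(signals.emg)
    fs = filtered.sampling_rate
    burst_rows = []
    summary_rows = []
    for ch in filtered.channel_names:
        raw = filtered.channel(ch)
        env = moving_rms(raw, fs)
        per_set_runs: dict[str, list] = {f"set{s + 1}": []
                                         for s in range(signals.schedule.n_sets)}
        for s, k, start, end in signals.schedule.run_windows():
            set_name = f"set{s + 1}"
            q0 = filtered.index_of(start - 3.0)
            q1 = filtered.index_of(start - 0.05)
            w0 = filtered.index_of(start)
            w1 = filtered.index_of(end)
            bursts = detect_bursts(env[w0:w1], fs, raw[q0:q1], t0=start, channel=ch)
            try:
                strides = select_strides(bursts, k=5)
            except InsufficientStridesError:
                logger.warning("excluding run: %s %s %s run %d on %s (%d bursts)",
                               signals.subject_id, signals.condition, set_name, k,
                               ch, len(bursts))
                per_set_runs[set_name].append(None)
                continue
            normalized = [normalize_amplitude(b.mean_rms, refs[ch]) for b in strides]
            per_set_runs[set_name].append(normalized)
            for b, pct in zip(strides, normalized):
                burst_rows.append({
                    "subject_id": signals.subject_id, "condition": signals.condition,
                    "set": set_name, "run": k, "channel": ch,
                    "onset_s": b.onset, "offset_s": b.offset,
                    "peak_rms_uv": b.peak_rms, "mean_rms_uv": b.mean_rms,
                    "normalized_pct": pct,
                })
        for set_name, runs in per_set_runs.items():
            summary_rows.append({
                "subject_id": signals.subject_id, "condition": signals.condition,
                "set": set_name, "channel": ch,
                "normalized_pct": summarize_set(runs),
            })
    return pd.DataFrame(burst_rows), pd.DataFrame(summary_rows)


def process_nirs_trial(signals: TrialSignals) -> pd.DataFrame:
    """Per-site, per-set Hbdiff summaries (mean and plateau, uM from baseline)."""
    rows = []
    for site, trace in signals.nirs.items():
        hbdiff = delta_from_baseline(trace, compute_hbdiff(trace.hbo2, trace.hhb))
        for s in range(signals.schedule.n_sets):
            window = signals.schedule.set_window(s)
            mean, plateau = set_summary(trace, hbdiff, window)
            rows.append({
                "subject_id": signals.subject_id, "condition": signals.condition,
                "site": site, "set": f"set{s + 1}",
                "mean_hbdiff_um": mean, "plateau_hbdiff_um": plateau,
            })
    return pd.DataFrame(rows)


def process_breath_trial(signals: TrialSignals, vo2max: float) -> pd.DataFrame:
    """Per-set oxygen uptake as %VO2max from 5-s averaged breath data."""
    t_end = signals.schedule.total_duration_s
    bin_times, bin_means = resample_breaths(signals.breath, t_start=0.0, t_end=t_end)
    rows = []
    for s in range(signals.schedule.n_sets):
        start, end = signals.schedule.set_window(s)
        mask = (bin_times >= start) & (bin_times < end)
        rows.append({
            "subject_id": signals.subject_id, "condition": signals.condition,
            "set": f"set{s + 1}",
            "vo2_pct_max": percent_vo2max(bin_means[mask], vo2max),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outcome assembly


def _outcome_row(subject_id, condition, timepoint, outcome, value, units):
    return {"subject_id": subject_id, "condition": condition, "timepoint": timepoint,
            "outcome": outcome, "value": value, "units": units}


def assemble_outcome_table(scalar_outcomes: pd.DataFrame, emg_summaries: pd.DataFrame,
                           nirs_summaries: pd.DataFrame, vo2_summaries: pd.DataFrame
                           ) -> pd.DataFrame:
    """One value per (subject, condition, timepoint, outcome).

    Scalar inputs are reduced here: jump heights are averaged over the two
    trials and converted to percent decrements against the pre-test jump;
    lactate concentrations become per-set accumulations.
    """
    rows = []
    for (subj, cond), grp in scalar_outcomes.groupby(["subject_id", "condition"],
                                                     sort=True):
        la = grp[grp.outcome == "lactate"].set_index("timepoint").value
        for tp in ("set1", "set2"):
            rows.append(_outcome_row(subj, cond, tp, "delta_lactate",
                                     delta_lactate(la[tp], la["pre"]), "mmol/L"))
        for _, r in grp[grp.outcome == "rpe"].iterrows():
            rows.append(_outcome_row(subj, cond, r.timepoint, "rpe", r.value, "0-10"))
        for jump, dec_name in (("cmj_height", "cmj_dec"), ("dj_height", "dj_dec")):
            jh = grp[grp.outcome == jump].groupby("timepoint").value.mean()
            pre = jh["pre"]
            for tp in jh.index:
                rows.append(_outcome_row(subj, cond, tp, jump, jh[tp], "cm"))
                if tp != "pre":
                    rows.append(_outcome_row(
                        subj, cond, tp, dec_name,
                        jump_percent_decrement(jh[tp], pre), "%"))
    for _, r in emg_summaries.iterrows():
        rows.append(_outcome_row(r.subject_id, r.condition, r["set"],
                                 f"rms_{r.channel.lower()}", r.normalized_pct, "%"))
    for _, r in nirs_summaries.iterrows():
        rows.append(_outcome_row(r.subject_id, r.condition, r["set"],
                                 NIRS_OUTCOME[r.site], r.mean_hbdiff_um, "uM"))
    for _, r in vo2_summaries.iterrows():
        rows.append(_outcome_row(r.subject_id, r.condition, r["set"],
                                 "vo2_pct_max", r.vo2_pct_max, "%"))
    df = pd.DataFrame(rows)
    return df.sort_values(["outcome", "subject_id", "condition", "timepoint"],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Inference


def _paired_vectors(table: pd.DataFrame, outcome: str, condition: str,
                    timepoints: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    sub = table[(table.outcome == outcome) & (table.condition == condition)]
    piv = sub.pivot_table(index="subject_id", columns="timepoint", values="value")
    piv = piv.dropna(subset=list(timepoints))
    return piv[timepoints[0]].to_numpy(), piv[timepoints[1]].to_numpy()


def _condition_summary(table: pd.DataFrame, outcome: str, condition: str,
                       timepoints: list[str]) -> pd.Series:
    sub = table[(table.outcome == outcome) & (table.condition == condition)
                & (table.timepoint.isin(timepoints))]
    return sub.groupby("subject_id").value.mean()


def run_inference(table: pd.DataFrame, mbi_config: MbiConfig | None = None
                  ) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """All magnitude-based comparisons for a complete outcome table.

    For every outcome with per-set values: set 2 vs set 1 within each
    condition, and COD vs SL on each subject's mean across sets.  The
    smallest worthwhile change always comes from the between-subject SD of
    the straight-line reference values.
    """
    mbi_config = mbi_config or MbiConfig()
    results: list[tuple[str, str, ComparisonResult]] = []
    outcomes = sorted(set(table.outcome) - {"lactate", "cmj_height", "dj_height"})
    for outcome in outcomes:
        log_scale = outcome not in RAW_SCALE_OUTCOMES
        sub = table[table.outcome == outcome]
        set_tps = [tp for tp in ("set1", "set2") if (sub.timepoint == tp).any()]
        if len(set_tps) == 2:
            sl_ref, _ = _paired_vectors(table, outcome, "SL", ("set1", "set2"))
            for cond in CONDITIONS:
                v1, v2 = _paired_vectors(table, outcome, cond, ("set1", "set2"))
                res = compare_paired(v1, v2, outcome=outcome, config=mbi_config,
                                     log_scale=log_scale, reference_values=sl_ref)
                results.append((f"set2_vs_set1_{cond}", cond, res))
        sl = _condition_summary(table, outcome, "SL", set_tps)
        cod = _condition_summary(table, outcome, "COD", set_tps)
        common = sl.index.intersection(cod.index)
        res = compare_paired(sl[common].to_numpy(), cod[common].to_numpy(),
                             outcome=outcome, config=mbi_config, log_scale=log_scale,
                             reference_values=sl[common].to_numpy())
        results.append(("cod_vs_sl", "both", res))

    rows = []
    flat = []
    for comparison, cond, res in results:
        flat.append(res)
        rows.append({
            "outcome": res.outcome, "comparison": comparison, "condition": cond,
            "mean_diff_pct": res.mean_diff_pct, "sd_diff_pct": res.sd_diff_pct,
            "p_greater": res.p_greater, "p_similar": res.p_similar,
            "p_lower": res.p_lower, "label": res.label, "n": res.n,
            "scale": "log" if res.log_scale else "raw",
        })
    return pd.DataFrame(rows), flat


# ---------------------------------------------------------------------------
# Full study


def write_report(comparisons: pd.DataFrame, cohort_df: pd.DataFrame,
                 intensity_df: pd.DataFrame, path: Path) -> None:
    lines = ["Synthetic HIE study: straight-line vs change-of-direction", ""]
    ratio = cohort_df.sprint_ratio
    dist = cohort_df.cod_distance_m
    lines.append(f"n = {len(cohort_df)} subjects")
    lines.append(f"sprint-time ratio SL/COD: {ratio.mean():.2f} ± {ratio.std(ddof=1):.2f}")
    lines.append(f"adjusted COD distance:    {dist.mean():.1f} ± {dist.std(ddof=1):.1f} m "
                 f"(base 22 m)")
    for cond, grp in intensity_df.groupby("condition"):
        lines.append(f"{cond} average intensity:    "
                     f"{grp.pct_mss.mean():.1f} ± {grp.pct_mss.std(ddof=1):.1f} %MSS, "
                     f"{grp.pct_vvo2max.mean():.1f} ± {grp.pct_vvo2max.std(ddof=1):.1f} %vVO2max")
    lines.append("")
    for comparison, grp in comparisons.groupby("comparison", sort=True):
        lines.append(f"[{comparison}]")
        for _, r in grp.iterrows():
            unit = "%" if r.scale == "log" else ""
            triple = "/".join(str(int(round(100 * p)))
                              for p in (r.p_greater, r.p_similar, r.p_lower))
            lines.append(f"  {r.outcome:<14} {r.mean_diff_pct:+7.1f} ± "
                         f"{r.sd_diff_pct:5.1f}{unit}  ({triple})  {r.label}")
        lines.append("")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")


def run_study(config: GeneratorConfig, out_dir: Path, seed: int | None = None,
              mbi_config: MbiConfig | None = None) -> RunManifest:
    """Execute generate -> process -> infer -> report; returns the manifest.

    Identical seed and config give byte-identical output tables.  On stage
    failure the manifest (with the failing stage recorded) is still written
    and the exception re-raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    manifest = RunManifest(seed=config.seed, out_dir=str(out_dir))
    t_start = time.time()
    try:
        cohort = generate_cohort(config)
        cohort_df = cohort_table(cohort)
        write_table(cohort_df, out_dir / "cohort.tsv")
        sched_frames = [schedule_table(build_hie_schedule(c, cohort), c)
                        for c in CONDITIONS]
        write_table(pd.concat(sched_frames, ignore_index=True),
                    out_dir / "schedule.tsv")
        scalar_outcomes, scalar_truth = generate_outcomes(cohort, config)
        write_table(scalar_truth, out_dir / "truth_outcomes.tsv")
        manifest.record("generate", "ok", subjects=len(cohort),
                        scalar_rows=len(scalar_outcomes))

        burst_frames, emg_frames, nirs_frames, vo2_frames = [], [], [], []
        truth_frames = {"strides": [], "set_amplitudes": [], "nirs_plateau": [],
                        "vo2": []}
        intensity_rows = []
        for profile in cohort:
            refs = emg_reference(profile, config)
            breath, speeds, _dur = generate_incremental_test(profile, config)
            bt, bv = resample_breaths(breath, t_start=0.0, t_end=5.0 * speeds.size)
            vo2max_est, vvo2max_est = determine_vo2max_vvo2max(bt, bv, speeds)
            for condition in CONDITIONS:
                signals = generate_trial_signals(profile, condition, config)
                bursts, emg_sum = process_emg_trial(signals, refs)
                burst_frames.append(bursts)
                emg_frames.append(emg_sum)
                nirs_frames.append(process_nirs_trial(signals))
                vo2_frames.append(process_breath_trial(signals, vo2max_est))
                for key, df in (("strides", signals.truth.strides),
                                ("set_amplitudes", signals.truth.set_amplitudes),
                                ("nirs_plateau", signals.truth.nirs_plateau),
                                ("vo2", signals.truth.vo2)):
                    df = df.copy()
                    df.insert(0, "condition", condition)
                    df.insert(0, "subject_id", profile.subject_id)
                    truth_frames[key].append(df)
                sched = signals.schedule
                pct_mss, pct_vvo2 = relative_intensity(
                    sched.run_distance_m, sched.run_duration_s,
                    profile.mss, profile.vvo2max)
                intensity_rows.append({
                    "subject_id": profile.subject_id, "condition": condition,
                    "distance_m": sched.run_distance_m, "pct_mss": pct_mss,
                    "pct_vvo2max": pct_vvo2, "vo2max_est": vo2max_est,
                    "vvo2max_est_kmh": vvo2max_est,
                })
        burst_table = pd.concat(burst_frames, ignore_index=True)
        emg_summaries = pd.concat(emg_frames, ignore_index=True)
        nirs_summaries = pd.concat(nirs_frames, ignore_index=True)
        vo2_summaries = pd.concat(vo2_frames, ignore_index=True)
        intensity_df = pd.DataFrame(intensity_rows)
        write_table(burst_table, out_dir / "bursts.tsv")
        write_table(emg_summaries, out_dir / "emg_set_summaries.tsv")
        write_table(nirs_summaries, out_dir / "nirs_set_summaries.tsv")
        write_table(vo2_summaries, out_dir / "vo2_set_summaries.tsv")
        write_table(intensity_df, out_dir / "relative_intensity.tsv")
        for key, frames in truth_frames.items():
            write_table(pd.concat(frames, ignore_index=True),
                        out_dir / f"truth_{key}.tsv")
        outcome_table = assemble_outcome_table(scalar_outcomes, emg_summaries,
                                               nirs_summaries, vo2_summaries)
        write_table(outcome_table, out_dir / "outcomes.tsv")
        manifest.record("process", "ok", bursts=len(burst_table),
                        outcome_rows=len(outcome_table))

        comparisons, _ = run_inference(outcome_table, mbi_config)
        write_table(comparisons, out_dir / "comparisons.tsv")
        manifest.record("infer", "ok", comparisons=len(comparisons))

        write_report(comparisons, cohort_df, intensity_df, out_dir / "summary.txt")
        logger.info("pipeline finished in %.1f s", time.time() - t_start)
        manifest.record("report", "ok")
    except Exception:
        manifest.record("failed", "error")
        manifest.write(out_dir / "manifest.json")
        raise
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Validation


def validate_inputs(dataset_dir: Path) -> list[str]:
    """Schema and consistency checks on a generated dataset directory.

    Collects every violation instead of stopping at the first; unreadable
    files are reported, not raised.
    """
    from .io import read_table, _read_signal

    dataset_dir = Path(dataset_dir)
    violations: list[str] = []
    if not dataset_dir.is_dir():
        return [f"{dataset_dir}: not a directory"]

    cohort_path = dataset_dir / "cohort.tsv"
    if not cohort_path.exists():
        violations.append("cohort.tsv: missing")
    else:
        try:
            cohort = read_table(cohort_path)
            required = {"subject_id", "t_sprint_sl_s", "t_sprint_cod_s"}
            missing = required - set(cohort.columns)
            if missing:
                violations.append(f"cohort.tsv: missing columns {sorted(missing)}")
            elif (cohort.t_sprint_cod_s <= cohort.t_sprint_sl_s).any():
                violations.append("cohort.tsv: t_sprint_cod must exceed t_sprint_sl")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            violations.append(f"cohort.tsv: unreadable ({exc})")

    outcomes_path = dataset_dir / "outcomes.tsv"
    if outcomes_path.exists():
        try:
            oc = read_table(outcomes_path)
            required = {"subject_id", "condition", "timepoint", "outcome", "value"}
            missing = required - set(oc.columns)
            if missing:
                violations.append(f"outcomes.tsv: missing columns {sorted(missing)}")
            else:
                dupes = oc.duplicated(["subject_id", "condition", "timepoint", "outcome"])
                if dupes.any():
                    violations.append(f"outcomes.tsv: {int(dupes.sum())} duplicate keys")
                rpe = oc[oc.outcome == "rpe"].value
                if ((rpe < 0) | (rpe > 10)).any():
                    violations.append("outcomes.tsv: RPE outside [0, 10]")
        except Exception as exc:  # noqa: BLE001
            violations.append(f"outcomes.tsv: unreadable ({exc})")

    signals_dir = dataset_dir / "signals"
    if signals_dir.is_dir():
        for path in sorted(signals_dir.glob("emg_*.tsv")):
            try:
                rate, header, data = _read_signal(path)
                channels = tuple(header[1:])
                missing = set(CHANNELS) - set(channels)
                if missing:
                    violations.append(f"{path.name}: missing channels {sorted(missing)}")
                if data.shape[0] >= 2:
                    dt = data[1, 0] - data[0, 0]
                    if dt > 0 and abs(1.0 / dt - rate) > 0.01 * rate:
                        violations.append(
                            f"{path.name}: declared {rate:g} Hz but spacing implies "
                            f"{1.0 / dt:.3g} Hz")
            except Exception as exc:  # noqa: BLE001
                violations.append(f"{path.name}: unreadable ({exc})")
        for path in sorted(signals_dir.glob("nirs_*.tsv")):
            try:
                rate, _, data = _read_signal(path)
                if data.shape[0] >= 2:
                    dt = data[1, 0] - data[0, 0]
                    if dt > 0 and abs(1.0 / dt - rate) > 0.01 * rate:
                        violations.append(
                            f"{path.name}: declared {rate:g} Hz but spacing implies "
                            f"{1.0 / dt:.3g} Hz")
            except Exception as exc:  # noqa: BLE001
                violations.append(f"{path.name}: unreadable ({exc})")
    return violations


def configure_logging(log_path: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_path is not None:
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
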