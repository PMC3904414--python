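"""Configuration objects for the synthetic cohort generator and the inference engine.

All randomness in the package flows from a single root seed held in
:class:`GeneratorConfig`; per-subject and per-trial streams are spawned from it
so that any subset of the data can be regenerated independently and
deterministically.

Effect sizes are expressed in percent and applied multiplicatively on the
natural-log scale, so that the log-transform assumed by the inference engine
holds exactly in the generated data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: EMG channel names: the eight lower-limb muscles recorded in each condition.
#: AL adductor longus, VL vastus lateralis, VM vastus medialis,
#: ST semitendinosus, BF biceps femoris, MG medial gastrocnemius,
#: LG lateral gastrocnemius, GM gluteus medius.
CHANNELS = ("AL", "VL", "VM", "ST", "BF", "MG", "LG", "GM")

#: NIRS probe sites.
NIRS_SITES = ("vastus_lateralis", "biceps_femoris")

#: Running conditions: straight-line and change-of-direction.
CONDITIONS = ("SL", "COD")

SETS = ("set1", "set2")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _pct_to_log(pct: float) -> float:
    """Convert a percent effect (or SD) to its natural-log-scale equivalent."""
    import math

    return math.log1p(pct / 100.0)


@dataclass
class EffectSpec:
    """Effect structure for one scalar outcome.

    Percentages describe multiplicative effects: ``condition_pct`` is the
    COD-vs-SL difference, ``timepoint_pct`` maps each timepoint to its effect
    relative to the outcome's reference timepoint, ``between_sd_pct`` is the
    between-subject spread of the baseline and ``within_sd_pct`` the
    trial-to-trial noise.
    """

    baseline: float
    units: str
    condition_pct: float = 0.0
    condition_sd_pct: float = 0.0
    timepoint_pct: dict[str, float] = field(default_factory=dict)
    timepoint_sd_pct: dict[str, float] = field(default_factory=dict)
    between_sd_pct: float = 10.0
    within_sd_pct: float = 3.0

    def validate(self) -> None:
        for name in ("condition_sd_pct", "between_sd_pct", "within_sd_pct"):
            if getattr(self, name) < 0:
                raise ConfigError(f"EffectSpec.{name} must be >= 0")
        if self.baseline <= 0:
            raise ConfigError("EffectSpec.baseline must be > 0")


@dataclass
class EmgSpec:
    """Waveform parameters of the synthetic surface-EMG generator.

    Each stride produces a raised-cosine amplitude envelope of
    ``burst_duration_s`` riding on a multi-tone carrier inside the 20-450 Hz
    analysis band; ``amplitude_uv`` is the per-muscle RMS amplitude of a run
    contraction at full (unfatigued) effort and ``decrement_pct`` the per-set,
    per-condition change applied to it.  ``sprint_amplitude_uv`` scales the
    maximal-sprint reference contractions used for normalization.
    """

    sampling_rate_hz: float = 1000.0
    burst_duration_s: float = 0.2
    stride_interval_s: float = 0.28
    sprint_stride_interval_s: float = 0.28
    noise_sd_uv: float = 15.0
    jog_amplitude_uv: float = 40.0
    carrier_freqs_hz: tuple[float, ...] = (60.0, 110.0, 170.0, 260.0)
    amplitude_uv: dict[str, float] = field(
        default_factory=lambda: {
            "AL": 250.0, "VL": 350.0, "VM": 320.0, "ST": 300.0,
            "BF": 310.0, "MG": 340.0, "LG": 330.0, "GM": 280.0,
        }
    )
    #: Run amplitude at HIE pace as a fraction of the sprint reference.
    hie_rel_amplitude: float = 0.85
    #: Between-subject SD (percentage points) around each mean decrement.
    decrement_sd_pct: float = 6.0
    #: Per-condition, per-set amplitude change (%) relative to the unfatigued
    #: run amplitude.  The COD condition shows larger hamstring/calf declines.
    decrement_pct: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "SL": {
                "set1": {c: -5.0 for c in CHANNELS},
                "set2": {**{c: -8.0 for c in CHANNELS}, "MG": -12.0},
            },
            "COD": {
                "set1": {**{c: -5.0 for c in CHANNELS},
                         "ST": -15.0, "LG": -12.0, "VL": -16.0, "VM": -11.0},
                "set2": {**{c: -8.0 for c in CHANNELS},
                         "ST": -19.0, "LG": -16.0},
            },
        }
    )

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("EMG sampling rate must be > 0")
        if self.noise_sd_uv < 0:
            raise ConfigError("EMG noise SD must be >= 0")
        if self.burst_duration_s >= self.stride_interval_s:
            raise ConfigError("burst duration must be shorter than the stride interval")
        missing = set(CHANNELS) - set(self.amplitude_uv)
        if missing:
            raise ConfigError(f"EMG amplitudes missing for channels: {sorted(missing)}")


@dataclass
class NirsSpec:
    """Muscle-oxygenation (Hbdiff) kinetics of the synthetic NIRS generator.

    Hbdiff drops mono-exponentially (time constant ``tau_s``) to a plateau at
    the start of each set and recovers toward baseline between sets with the
    same time constant.  Plateaus are negative: more negative means greater
    deoxygenation.
    """

    sampling_rate_hz: float = 10.0
    tau_s: float = 10.0
    plateau_um: dict[str, float] = field(
        default_factory=lambda: {"vastus_lateralis": -8.0, "biceps_femoris": -6.0}
    )
    noise_sd_um: float = 0.3
    between_sd_pct: float = 15.0
    baseline_s: float = 30.0
    dpf: float = 3.83  # differential pathlength factor, carried as metadata

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("NIRS sampling rate must be > 0")
        if self.tau_s <= 0:
            raise ConfigError("NIRS time constant must be > 0")
        if self.noise_sd_um < 0:
            raise ConfigError("NIRS noise SD must be >= 0")


@dataclass
class BreathSpec:
    """Breath-by-breath oxygen-uptake generator.

    Set-level targets are expressed as a percentage of the subject's VO2max;
    the set-2 elevation (``set_effect_pct``) reflects the progressive rise in
    aerobic contribution across sets, larger with changes of direction.
    """

    mean_interval_s: float = 2.5
    interval_jitter_s: float = 0.4
    baseline_pct_vo2max: float = 25.0
    set1_pct_vo2max: dict[str, float] = field(
        default_factory=lambda: {"SL": 81.3, "COD": 79.9}
    )
    set_effect_pct: dict[str, float] = field(
        default_factory=lambda: {"SL": 5.4, "COD": 8.1}
    )
    set_effect_sd_pct: dict[str, float] = field(
        default_factory=lambda: {"SL": 2.5, "COD": 2.0}
    )
    between_sd_pct: float = 8.0
    breath_noise_pct: float = 4.0
    tau_on_s: float = 25.0
    tau_off_s: float = 40.0

    def validate(self) -> None:
        if self.mean_interval_s <= 0:
            raise ConfigError("breath interval must be > 0")
        if self.breath_noise_pct < 0:
            raise ConfigError("breath noise must be >= 0")


@dataclass
class CohortSpec:
    """Population parameters for the simulated amateur team-sport cohort."""

    mss_mean_ms: float = 6.4  # maximal sprint speed, m/s
    mss_sd_ms: float = 0.25
    vvo2max_mean_kmh: float = 15.1
    vvo2max_sd_kmh: float = 1.0
    vo2max_mean: float = 55.0  # mL/min/kg
    vo2max_sd: float = 5.0
    cmj_mean_cm: float = 37.3
    cmj_sd_cm: float = 4.5
    dj_mean_cm: float = 23.7
    dj_sd_cm: float = 6.2
    #: 22-m sprint average speed as a fraction of MSS (acceleration cost).
    sprint22_rel_speed: float = 0.95


def _default_effects() -> dict[str, EffectSpec]:
    return {
        "delta_lactate": EffectSpec(
            baseline=8.0, units="mmol/L",
            condition_pct=9.7, condition_sd_pct=10.4,
            timepoint_pct={"set1": 0.0, "set2": 10.0},
            timepoint_sd_pct={"set2": 11.0},
            between_sd_pct=45.0, within_sd_pct=4.0,
        ),
        "rpe": EffectSpec(
            baseline=6.0, units="0-10",
            condition_pct=0.0, condition_sd_pct=5.0,
            timepoint_pct={"set1": 0.0, "set2": 25.0},
            timepoint_sd_pct={"set2": 8.0},
            between_sd_pct=10.0, within_sd_pct=3.0,
        ),
        "cmj_height": EffectSpec(
            baseline=37.3, units="cm",
            condition_pct=0.0, condition_sd_pct=4.0,
            timepoint_pct={"pre": 0.0, "set1": -3.6, "set2": -3.3},
            timepoint_sd_pct={"set1": 6.0, "set2": 7.0},
            between_sd_pct=12.0, within_sd_pct=2.0,
        ),
        "dj_height": EffectSpec(
            baseline=23.7, units="cm",
            condition_pct=0.0, condition_sd_pct=4.0,
            timepoint_pct={"pre": 0.0, "set1": -6.7, "set2": -6.8},
            timepoint_sd_pct={"set1": 7.5, "set2": 10.5},
            between_sd_pct=26.0, within_sd_pct=2.5,
        ),
    }


@dataclass
class GeneratorConfig:
    """Root configuration for the synthetic study.

    Defaults reproduce the study conditions: eleven subjects, a straight-line
    to COD 22-m sprint-time ratio of 0.75 +/- 0.02, and effect sizes anchored
    to the reported group outcomes (e.g. +9.7 +/- 10.4% blood-lactate
    accumulation with COD, +8.1% set-2 oxygen-uptake elevation).
    """

    n_subjects: int = 11
    seed: int = 12345
    sl_cod_ratio_mean: float = 0.75
    sl_cod_ratio_sd: float = 0.02
    lactate_pre_mmol: float = 2.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: dict[str, EffectSpec] = field(default_factory=_default_effects)
    emg: EmgSpec = field(default_factory=EmgSpec)
    nirs: NirsSpec = field(default_factory=NirsSpec)
    breath: BreathSpec = field(default_factory=BreathSpec)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not (0.0 < self.sl_cod_ratio_mean < 1.0):
            raise ConfigError("sprint-time ratio mean must lie in (0, 1)")
        if self.sl_cod_ratio_sd < 0:
            raise ConfigError("sprint-time ratio SD must be >= 0")
        for spec in self.effects.values():
            spec.validate()
        self.emg.validate()
        self.nirs.validate()
        self.breath.validate()


@dataclass
class MbiConfig:
    """Magnitude-based inference settings.

    ``swc_multiplier`` scales the between-subject SD into the smallest
    worthwhile change (Cohen's small-effect convention, 0.2).  An effect is
    labelled "unclear" when the chances of both a higher and a lower true
    value exceed ``unclear_threshold``.
    """

    swc_multiplier: float = 0.2
    unclear_threshold: float = 0.05

    def validate(self) -> None:
        if self.swc_multiplier <= 0:
            raise ConfigError("swc_multiplier must be > 0")
        if not (0.0 < self.unclear_threshold < 0.5):
            raise ConfigError("unclear_threshold must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# YAML round-trip


def _from_dict(cls, data: Mapping):
    """Build a dataclass from a (possibly partial) nested mapping."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key {key!r} for {cls.__name__}")
        if key == "effects":
            kwargs[key] = {name: _from_dict(EffectSpec, spec) for name, spec in value.items()}
        elif key == "cohort":
            kwargs[key] = _from_dict(CohortSpec, value)
        elif key == "emg":
            kwargs[key] = _from_dict(EmgSpec, value)
        elif key == "nirs":
            kwargs[key] = _from_dict(NirsSpec, value)
        elif key == "breath":
            kwargs[key] = _from_dict(BreathSpec, value)
        elif key == "carrier_freqs_hz":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: Mapping | None) -> GeneratorConfig:
    cfg = _from_dict(GeneratorConfig, data or {})
    cfg.validate()
    return cfg


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML file (missing keys use defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(cfg: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
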