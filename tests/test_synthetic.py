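"""Synthetic cohort and signal generator: determinism, configured structure,
and ground-truth sufficiency."""

import dataclasses

import numpy as np
import pytest

from hiecod.cardio import resample_breaths
from hiecod.config import CHANNELS, ConfigError, GeneratorConfig
from hiecod.synthetic import (generate_breath_trace, generate_cohort,
                              generate_outcomes, generate_sprint_recording,
                              generate_trial_signals)


class TestGenerateCohort:
    def test_seeded_determinism(self, default_config):
        c1 = generate_cohort(default_config)
        c2 = generate_cohort(GeneratorConfig())
        assert c1 == c2

    def test_zero_sd_gives_exact_ratio(self):
        cfg = GeneratorConfig(sl_cod_ratio_sd=0.0)
        for p in generate_cohort(cfg):
            assert p.sprint_ratio == pytest.approx(0.75)

    def test_large_sample_ratio_mean(self):
        # law of large numbers: with n = 1000 the sample mean ratio
        # concentrates tightly around the configured 0.75
        cfg = GeneratorConfig(n_subjects=1000)
        ratios = [p.sprint_ratio for p in generate_cohort(cfg)]
        assert np.mean(ratios) == pytest.approx(0.75, abs=0.002)

    def test_cod_sprint_always_slower(self):
        for seed in (1, 2, 3):
            for p in generate_cohort(GeneratorConfig(seed=seed)):
                assert p.t_sprint_cod > p.t_sprint_sl > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(GeneratorConfig(n_subjects=1))
        with pytest.raises(ConfigError):
            generate_cohort(GeneratorConfig(sl_cod_ratio_mean=1.2))


class TestTrialSignals:
    def test_bit_identical_for_fixed_seed(self, default_config):
        p = generate_cohort(default_config)[0]
        s1 = generate_trial_signals(p, "COD", default_config)
        s2 = generate_trial_signals(p, "COD", GeneratorConfig())
        assert np.array_equal(s1.emg.data, s2.emg.data)
        assert np.array_equal(s1.breath.values, s2.breath.values)
        assert np.array_equal(s1.nirs["biceps_femoris"].hhb,
                              s2.nirs["biceps_femoris"].hhb)

    def test_ground_truth_emitted_for_all_channels_and_sets(self, default_config):
        p = generate_cohort(default_config)[0]
        sig = generate_trial_signals(p, "SL", default_config)
        assert set(sig.truth.strides.channel) == set(CHANNELS)
        assert set(sig.truth.set_amplitudes["set"]) == {"set1", "set2"}
        assert len(sig.truth.strides) == 8 * 20 * 14  # 14 strides per 4-s run
        assert set(sig.truth.nirs_plateau.site) == {"vastus_lateralis",
                                                    "biceps_femoris"}

    def test_vo2_set_effect_applied(self, default_config):
        # with SD 0 the set-2 target exceeds set 1 by exactly the configured
        # effect, and the breath trace reproduces it within sampling error
        cfg = GeneratorConfig()
        cfg.breath.set_effect_sd_pct = {"SL": 0.0, "COD": 0.0}
        cfg.breath.breath_noise_pct = 0.0
        p = generate_cohort(cfg)[0]
        trace, truth = generate_breath_trace(p, "COD", cfg)
        target_ratio = 1.081
        assert truth.pct_vo2max[1] / truth.pct_vo2max[0] == pytest.approx(
            target_ratio, abs=1e-9)
        _, bins = resample_breaths(trace, t_start=0.0, t_end=460.0)
        m1 = np.nanmean(bins[:32])
        m2 = np.nanmean(bins[60:92])
        assert m2 / m1 == pytest.approx(target_ratio, abs=0.01)

    def test_nirs_plateau_matches_analytic_curve(self):
        cfg = GeneratorConfig()
        cfg.nirs.noise_sd_um = 0.0
        cfg.nirs.between_sd_pct = 0.0
        p = generate_cohort(cfg)[0]
        sig = generate_trial_signals(p, "SL", cfg)
        trace = sig.nirs["vastus_lateralis"]
        hbdiff = (trace.hbo2 - trace.hhb) / 2.0
        hbdiff = hbdiff - hbdiff[trace.times < 0].mean()
        plateau_cfg = cfg.nirs.plateau_um["vastus_lateralis"]
        second_half = hbdiff[(trace.times >= 80) & (trace.times < 160)]
        assert second_half.mean() == pytest.approx(plateau_cfg, rel=0.02)

    def test_sprint_recording_has_enough_strides(self, default_config):
        p = generate_cohort(default_config)[0]
        rec, truth = generate_sprint_recording(p, default_config)
        per_channel = truth.groupby("channel").size()
        assert (per_channel >= 5).all()
        assert rec.data.shape[0] == 8


def _zero_effect_config() -> GeneratorConfig:
    cfg = GeneratorConfig(n_subjects=3)
    for spec in cfg.effects.values():
        spec.condition_pct = 0.0
        spec.condition_sd_pct = 0.0
        spec.timepoint_pct = {tp: 0.0 for tp in spec.timepoint_pct}
        spec.timepoint_sd_pct = {}
        spec.within_sd_pct = 0.0
    return cfg


class TestGenerateOutcomes:
    def test_zero_effects_zero_noise_identical_conditions(self):
        outcomes, _ = generate_outcomes(generate_cohort(_zero_effect_config()),
                                        _zero_effect_config())
        piv = outcomes.pivot_table(index=["subject_id", "timepoint", "outcome",
                                          "trial"],
                                   columns="condition", values="value")
        assert np.allclose(piv["SL"], piv["COD"])

    def test_forced_condition_effect(self):
        cfg = _zero_effect_config()
        cfg.effects["delta_lactate"].condition_pct = 10.0
        cohort = generate_cohort(cfg)
        outcomes, _ = generate_outcomes(cohort, cfg)
        la = outcomes[outcomes.outcome == "lactate"].pivot_table(
            index=["subject_id", "timepoint"], columns="condition", values="value")
        pre = la.xs("pre", level="timepoint")
        for tp in ("set1", "set2"):
            delta = la.xs(tp, level="timepoint") - pre
            assert np.allclose(delta["COD"], 1.10 * delta["SL"])

    def test_large_sample_effect_recovery(self):
        # sampling oracle: the mean per-subject condition effect across 1000
        # subjects concentrates around the configured +9.7%
        cfg = GeneratorConfig(n_subjects=1000)
        _, truth = generate_outcomes(generate_cohort(cfg), cfg)
        eff = truth[(truth.outcome == "delta_lactate")
                    & (truth.param == "condition_effect_pct")].value
        assert eff.mean() == pytest.approx(9.7, abs=1.0)

    def test_empty_cohort_rejected(self, default_config):
        with pytest.raises(ValueError):
            generate_outcomes([], default_config)
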