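"""Generator contracts: protocol fidelity, injected-effect closed forms,
determinism and artifact behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mieeg import synthgen
from mieeg.spectral import band_power, periodogram
from mieeg.synthgen import ConfigurationError, GeneratorConfig

MU = (6.25, 12.5)


def band_power_window(trial_ch, sl, fs, band=MU):
    return band_power(periodogram(trial_ch[sl], fs), *band)


def post_pre_ratio(es, channel, label, band=MU):
    """Mean event/reference mu-band power ratio, windows clear of the ramp."""
    sub = es.select_label(label)
    ch = sub.channel_index(channel)
    cue = sub.cue_index
    fs = sub.fs
    pre = slice(cue - 150, cue - 50)
    post = slice(cue + 50, cue + 250)
    e = np.mean([band_power_window(sub.data[i, ch], post, fs, band)
                 for i in range(sub.n_trials)])
    r = np.mean([band_power_window(sub.data[i, ch], pre, fs, band)
                 for i in range(sub.n_trials)])
    return e / r


class TestPresets:
    def test_comp118_protocol(self):
        cfg = GeneratorConfig(preset="comp118", seed=3)
        assert cfg.fs == 100.0
        assert cfg.n_channels == 118
        assert cfg.n_trials_per_class == 140
        es = synthgen.generate_session(cfg)
        assert es.n_trials == 280
        assert es.class_counts() == {"left": 140, "right": 140}
        assert es.n_channels == 118
        assert "C3" in es.channel_names and "C4" in es.channel_names

    def test_lab32_preset_rates(self):
        cfg = GeneratorConfig(preset="lab32")
        assert cfg.fs == 250.0
        assert cfg.n_channels == 32

    def test_montage_must_contain_motor_electrodes(self):
        with pytest.raises(ConfigurationError, match="C3"):
            GeneratorConfig(preset="custom", channel_names=["Cz", "Pz", "Fz"])

    @pytest.mark.parametrize("field,value", [
        ("erd_depth", 1.5), ("erd_depth", -0.1), ("ers_gain", -0.5),
        ("epoch_window", (0.5, 3.0)), ("n_trials_per_class", 0),
    ])
    def test_invalid_configs_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**{field: value})


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        a = synthgen.generate_session(small_config)
        b = synthgen.generate_session(small_config)
        assert np.array_equal(a.data, b.data)
        assert list(a.labels) == list(b.labels)

    def test_make_trial_same_rng_state(self, small_config):
        t1 = synthgen.make_trial("left", small_config, np.random.default_rng(5))
        t2 = synthgen.make_trial("left", small_config, np.random.default_rng(5))
        assert np.array_equal(t1, t2)

    def test_seed_changes_data(self, small_config):
        a = synthgen.generate_session(small_config)
        b = synthgen.generate_session(dataclasses.replace(small_config, seed=8))
        assert not np.array_equal(a.data, b.data)


class TestInjectedEffect:
    def test_full_suppression_noiseless(self):
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=1.0,
                              snr_db=np.inf, seed=1)
        trial = synthgen.make_trial("left", cfg, np.random.default_rng(0))
        c4 = trial[cfg.channel_names.index("C4")]
        post = c4[cfg.cue_index + 50:]
        pre = c4[: cfg.cue_index - 50]
        # only sub-uV cross-talk from the (unsuppressed) C3 source remains
        assert np.max(np.abs(post)) < 0.1
        assert np.max(np.abs(pre)) > 100 * np.max(np.abs(post))

    def test_noiseless_power_ratio_closed_form(self):
        """erd_depth d suppresses post-cue power by exactly (1-d)."""
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=0.19,
                              ers_gain=0.0, snr_db=np.inf,
                              n_trials_per_class=10, seed=2)
        es = synthgen.generate_session(cfg)
        ratio = post_pre_ratio(es, "C4", "left")
        assert ratio == pytest.approx(0.81, abs=0.02)

    def test_mc_ratio_with_noise(self):
        """140 noisy trials: post/pre mu ratio at C4 = 1-d within 0.05."""
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=0.4,
                              n_trials_per_class=140, seed=3)
        es = synthgen.generate_session(cfg)
        assert post_pre_ratio(es, "C4", "left") == pytest.approx(0.60, abs=0.05)

    def test_no_effect_when_depth_zero(self):
        """erd_depth=ers_gain=0: class-conditional band power at C3/C4 is
        statistically indistinguishable (two-sample t, alpha=0.01)."""
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=0.0,
                              ers_gain=0.0, n_trials_per_class=100, seed=4)
        es = synthgen.generate_session(cfg)
        cue, fs = es.cue_index, es.fs
        post = slice(cue + 50, cue + 250)
        for ch_name in ("C3", "C4"):
            ch = es.channel_index(ch_name)
            p = {lab: [band_power_window(es.select_label(lab).data[i, ch], post, fs)
                       for i in range(100)] for lab in ("left", "right")}
            _, pval = stats.ttest_ind(p["left"], p["right"])
            assert pval > 0.01

    def test_label_symmetry(self):
        """Swapping labels mirrors the C3/C4 band-power pattern."""
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=0.5,
                              n_trials_per_class=60, seed=5)
        es = synthgen.generate_session(cfg)
        r_left_c4 = post_pre_ratio(es, "C4", "left")
        r_right_c3 = post_pre_ratio(es, "C3", "right")
        assert r_left_c4 == pytest.approx(r_right_c3, abs=0.06)

    def test_non_motor_channels_uninformative(self):
        cfg = GeneratorConfig(preset="custom", n_channels=8, erd_depth=0.8,
                              snr_db=np.inf, n_trials_per_class=10, seed=6)
        es = synthgen.generate_session(cfg)
        ratio = post_pre_ratio(es, "Cz", "left")
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestArtifacts:
    def test_noop_when_disabled(self, small_config):
        rng = np.random.default_rng(0)
        trial = synthgen.make_trial("left", small_config, rng)
        out = synthgen.inject_artifacts(trial, small_config, np.random.default_rng(1))
        assert np.array_equal(out, trial)
        assert out is not trial

    def test_line_noise_adds_spectral_peak(self):
        cfg = GeneratorConfig(preset="custom", n_channels=8, fs=250.0,
                              line_freq=50.0, snr_db=np.inf, seed=1)
        clean_cfg = dataclasses.replace(cfg, line_freq=None)
        rng = np.random.default_rng(2)
        clean = synthgen.make_trial("left", clean_cfg, rng)
        noisy = synthgen.inject_artifacts(clean, cfg, np.random.default_rng(3))
        ch = cfg.channel_names.index("Cz")
        p_clean = band_power(periodogram(clean[ch], 250.0), 49, 51)
        p_noisy = band_power(periodogram(noisy[ch], 250.0), 49, 51)
        assert p_noisy > 10 * max(p_clean, 1e-12)

    def test_line_at_nyquist_rejected(self):
        cfg = GeneratorConfig(preset="custom", n_channels=8, fs=100.0, seed=1)
        bad = dataclasses.replace(cfg, line_freq=50.0)
        trial = np.zeros((8, bad.n_samples))
        with pytest.raises(ConfigurationError, match="alias"):
            synthgen.inject_artifacts(trial, bad, np.random.default_rng(0))

    def test_blinks_hit_frontal_channels_hardest(self):
        cfg = GeneratorConfig(preset="custom", n_channels=32, blink_rate=30.0,
                              snr_db=np.inf, seed=1)
        rng = np.random.default_rng(4)
        trial = synthgen.make_trial("left", cfg, rng)
        fp1 = trial[cfg.channel_names.index("Fp1")]
        oz = trial[cfg.channel_names.index("Oz")]
        assert np.max(np.abs(fp1)) > 3 * np.max(np.abs(oz))
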