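"""Synthetic motor-imagery EEG sessions.

Generates labelled left/right-hand imagery epochs with the statistical
structure the downstream analysis assumes: mu (~10 Hz) and beta (~20 Hz)
sensorimotor rhythms sourced at C3/C4, contralateral event-related
desynchronization (ERD) and ipsilateral synchronization (ERS) after the cue,
1/f background noise, and optional blink / mains-line artifacts.

The generator is parameterised so that the injected effect has a closed
form: ``erd_depth`` is the fractional *power* reduction of the contralateral
rhythms after the cue, hence the expected ERD/ERS percentage at the
contralateral motor electrode is exactly ``-100 * erd_depth`` on the
noiseless rhythm component.  Two protocol presets mirror common acquisition
setups: ``comp118`` (118 electrodes, 100 Hz, 140 trials per class) and
``lab32`` (32 electrodes, 250 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import LABELS, EpochSet, config_hash


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


#: Curated 32-channel 10-20/10-10 montage used by the lab32 preset and as the
#: head of larger montages.  C3/C4 (the motor electrodes) come first.
CORE_32 = [
    "C3", "C4", "Cz", "C1", "C2", "C5", "C6",
    "FC3", "FC4", "FC1", "FC2", "CP3", "CP4", "CP1", "CP2",
    "F3", "F4", "F7", "F8", "Fz",
    "P3", "P4", "P7", "P8", "Pz",
    "T7", "T8", "Fp1", "Fp2", "O1", "O2", "Oz",
]

# Rhythm peak amplitudes in microvolts; scalp sensorimotor rhythms are of
# order 10 uV, beta smaller than mu.
MU_AMPLITUDE_UV = 10.0
BETA_AMPLITUDE_UV = 5.0
#: Raised-cosine transition length at the cue, seconds.
RAMP_SECONDS = 0.25
#: Spatial decay length (m) of source -> electrode gain on the scalp.
SPATIAL_LAMBDA_M = 0.04
BLINK_AMPLITUDE_UV = 100.0
BLINK_SIGMA_S = 0.1
LINE_AMPLITUDE_UV = 2.0


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    """3-D electrode positions (m) from the standard 10-05 montage."""
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage alias naming differs across mne versions
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    return {name: np.asarray(p, dtype=float) for name, p in pos.items()}


def default_channel_names(n_channels: int) -> list[str]:
    """Deterministic montage of ``n_channels`` 10-20/10-05 labels incl. C3/C4."""
    if n_channels < 2:
        raise ConfigurationError("need at least 2 channels (C3 and C4)")
    pos = _montage_positions()
    names = [c for c in CORE_32 if c in pos][:n_channels]
    if n_channels <= len(names):
        names = names[:n_channels]
    else:
        extra = [c for c in pos if c not in names]
        names = names + extra[: n_channels - len(names)]
    if len(names) < n_channels:
        raise ConfigurationError(
            f"standard montage has only {len(names)} labels, "
            f"cannot build {n_channels} channels"
        )
    if "C3" not in names or "C4" not in names:
        raise ConfigurationError("montage must include C3 and C4")
    return names


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic session.

    ``erd_depth`` is the fractional reduction of contralateral mu+beta band
    *power* during imagery (0 = no effect, 1 = full suppression);
    ``ers_gain`` the fractional ipsilateral power increase.  ``snr_db`` is
    the ratio of rhythm power to broadband background power at C3/C4
    (``inf`` disables noise).
    """

    preset: str = "custom"
    n_trials_per_class: int = 140
    fs: float = 100.0
    n_channels: int = 32
    channel_names: list[str] | None = None
    epoch_window: tuple[float, float] = (-2.0, 3.5)
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_depth: float = 0.4
    ers_gain: float = 0.1
    noise_exponent: float = 1.0
    snr_db: float = 10.0
    blink_rate: float = 0.0
    line_freq: float | None = None
    seed: int = 0

    # Protocol presets: fixed acquisition parameters.
    _PRESETS = {
        "comp118": dict(fs=100.0, n_channels=118, n_trials_per_class=140),
        "lab32": dict(fs=250.0, n_channels=32),
    }

    def __post_init__(self) -> None:
        if self.preset not in ("custom", *self._PRESETS):
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        for key, val in self._PRESETS.get(self.preset, {}).items():
            setattr(self, key, val)
        self.epoch_window = tuple(float(v) for v in self.epoch_window)
        if self.channel_names is None:
            self.channel_names = default_channel_names(self.n_channels)
        else:
            self.channel_names = list(self.channel_names)
            self.n_channels = len(self.channel_names)
        if "C3" not in self.channel_names or "C4" not in self.channel_names:
            raise ConfigurationError("channel_names must include C3 and C4")
        pos = _montage_positions()
        missing = [c for c in self.channel_names if c not in pos]
        if missing:
            raise ConfigurationError(
                f"channels without a standard 10-05 position: {missing}"
            )
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ConfigurationError("ers_gain must be >= 0")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        a, b = self.epoch_window
        if not a < 0.0 < b:
            raise ConfigurationError(
                f"epoch window {self.epoch_window} must span the cue at t=0"
            )
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be >= 1")
        if self.blink_rate < 0:
            raise ConfigurationError("blink_rate must be >= 0")

    # -- derived quantities ---------------------------------------------
    @property
    def n_samples(self) -> int:
        a, b = self.epoch_window
        return int(round((b - a) * self.fs))

    @property
    def cue_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.fs))

    def times(self) -> np.ndarray:
        a, _ = self.epoch_window
        return a + np.arange(self.n_samples) / self.fs


def _power_ramp(t: np.ndarray, target: float) -> np.ndarray:
    """Power modulation profile: 1 before the cue, ``target`` after, joined
    by a raised-cosine ramp of RAMP_SECONDS."""
    w = np.clip(t / RAMP_SECONDS, 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(np.pi * w))
    return 1.0 + (target - 1.0) * w


def _rhythm(t, mu_freq, beta_freq, phases, gain: np.ndarray | float):
    amp = np.sqrt(gain)
    return amp * (
        MU_AMPLITUDE_UV * np.sin(2 * np.pi * mu_freq * t + phases[0])
        + BETA_AMPLITUDE_UV * np.sin(2 * np.pi * beta_freq * t + phases[1])
    )


def _one_over_f_noise(n, fs, exponent, rng) -> np.ndarray:
    """Unit-variance 1/f^exponent noise of length n."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    f_min = 0.5  # flatten below 0.5 Hz to keep the spectrum integrable
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_min) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = shape * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spatial_gains(channel_names: list[str], source: str) -> np.ndarray:
    """Gaussian-in-distance gain of a scalp source at electrode ``source``."""
    pos = _montage_positions()
    src = pos[source]
    d = np.array([np.linalg.norm(pos[c] - src) for c in channel_names])
    return np.exp(-(d**2) / (2 * SPATIAL_LAMBDA_M**2))


def make_trial(label: str, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Single-trial kernel: one ``[channel, sample]`` array in microvolts.

    The trial is the sum of (i) mu+beta rhythms sourced at C3 and C4 with a
    smooth post-cue power modulation — contralateral ``x(1-erd_depth)``,
    ipsilateral ``x(1+ers_gain)`` — (ii) the *unmodulated* rhythms spatially
    mixed onto all non-motor electrodes (class-uninformative by
    construction), (iii) per-channel 1/f noise scaled to ``snr_db``, and
    (iv) optional artifacts (see :func:`inject_artifacts`).
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    t = config.times()
    names = config.channel_names
    i_c3, i_c4 = names.index("C3"), names.index("C4")

    # contralateral control: left-hand imagery modulates the right hemisphere (C4)
    factors = {
        "left": {"C3": 1.0 + config.ers_gain, "C4": 1.0 - config.erd_depth},
        "right": {"C3": 1.0 - config.erd_depth, "C4": 1.0 + config.ers_gain},
    }[label]

    phases = {src: rng.uniform(0, 2 * np.pi, size=2) for src in ("C3", "C4")}
    modulated = {
        src: _rhythm(
            t, config.mu_freq, config.beta_freq, phases[src],
            _power_ramp(t, factors[src]),
        )
        for src in ("C3", "C4")
    }
    flat = {
        src: _rhythm(t, config.mu_freq, config.beta_freq, phases[src], 1.0)
        for src in ("C3", "C4")
    }

    gains = {src: _spatial_gains(names, src) for src in ("C3", "C4")}
    trial = np.empty((config.n_channels, config.n_samples))
    for ch in range(config.n_channels):
        if ch in (i_c3, i_c4):
            trial[ch] = (
                gains["C3"][ch] * modulated["C3"] + gains["C4"][ch] * modulated["C4"]
            )
        else:
            trial[ch] = gains["C3"][ch] * flat["C3"] + gains["C4"][ch] * flat["C4"]

    if np.isfinite(config.snr_db):
        rhythm_power = (MU_AMPLITUDE_UV**2 + BETA_AMPLITUDE_UV**2) / 2.0
        noise_power = rhythm_power / 10.0 ** (config.snr_db / 10.0)
        sigma = math.sqrt(noise_power)
        for ch in range(config.n_channels):
            trial[ch] += sigma * _one_over_f_noise(
                config.n_samples, config.fs, config.noise_exponent, rng
            )

    return inject_artifacts(trial, config, rng)


def inject_artifacts(
    trial: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add blink transients (frontal, <= 4 Hz) and mains-line interference.

    Returns a modified copy; with ``blink_rate=0`` and no ``line_freq`` the
    copy is identical to the input.  A ``line_freq`` at or above Nyquist is
    rejected (it would alias rather than appear at its own frequency).
    """
    if config.blink_rate < 0:
        raise ConfigurationError("blink_rate must be >= 0")
    if config.line_freq is not None and config.line_freq >= config.fs / 2:
        raise ConfigurationError(
            f"line_freq {config.line_freq} Hz >= Nyquist {config.fs / 2} Hz "
            "would alias; filter or choose a lower frequency"
        )
    out = trial.copy()
    t = config.times()
    duration_min = (t[-1] - t[0] + 1.0 / config.fs) / 60.0

    if config.blink_rate > 0:
        # blink source just above the nasion; Gaussian bump, ~1.6 Hz bandwidth
        gains = _spatial_gains(config.channel_names, "Fpz")
        n_blinks = rng.poisson(config.blink_rate * duration_min)
        for _ in range(n_blinks):
            t0 = rng.uniform(t[0], t[-1])
            bump = BLINK_AMPLITUDE_UV * np.exp(-((t - t0) ** 2) / (2 * BLINK_SIGMA_S**2))
            out += gains[:, None] * bump[None, :]

    if config.line_freq is not None:
        phase = rng.uniform(0, 2 * np.pi)
        out += LINE_AMPLITUDE_UV * np.sin(2 * np.pi * config.line_freq * t + phase)[None, :]

    return out


def generate_session(config: GeneratorConfig) -> EpochSet:
    """Generate one labelled session; deterministic for a fixed config+seed.

    Emits ``2 * n_trials_per_class`` trials in a seeded random class order
    (balanced by construction).
    """
    rng = np.random.default_rng(config.seed)
    labels = np.array(
        ["left"] * config.n_trials_per_class + ["right"] * config.n_trials_per_class,
        dtype=object,
    )
    labels = labels[rng.permutation(len(labels))]
    data = np.stack([make_trial(lab, config, rng) for lab in labels])
    return EpochSet(
        data=data,
        labels=labels,
        fs=config.fs,
        channel_names=list(config.channel_names),
        cue_index=config.cue_index,
        provenance={
            "generator": "mieeg.synthgen",
            "config_hash": config_hash(config),
            "seed": config.seed,
            "preset": config.preset,
        },
    )
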