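"""Event-related desynchronization / synchronization quantification.

ERD/ERS compares band energy after the cue (E, the event window) with band
energy before it (R, the reference window):

    ERD/ERS % = 100 * (E - R) / R

Negative values are desynchronization (contralateral power drop during
imagery), positive values synchronization.  Band energies are periodogram
band powers times window duration (uV^2 * s); for session-level maps, E and
R are averaged across trials *before* taking the ratio, the standard
low-variance ERD estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EpochSet
from .spectral import band_power, periodogram

#: Default analysis bands (Hz), the dyadic mu/alpha and beta ranges of the
#: 3-level db6 scheme at 100 Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "mu": (6.25, 12.5),
    "beta": (12.5, 25.0),
}
#: Default windows in seconds relative to the cue; both clear of the
#: modulation ramp at t=0.
DEFAULT_REF_WINDOW = (-1.5, -0.5)
DEFAULT_EVENT_WINDOW = (0.5, 2.5)
#: Minimum window length, in cycles of the band's lower edge, for a usable
#: band-energy estimate.
MIN_CYCLES = 4.0


@dataclass
class ErdErsResult:
    """Trial-averaged ERD/ERS percentages per (channel, band).

    ``table`` columns: channel, band, f_lo, f_hi, E, R, erd_ers_percent.
    """

    table: pd.DataFrame
    ref_window: tuple[float, float]
    event_window: tuple[float, float]
    label: str
    n_trials: int

    def percent(self, channel: str, band: str) -> float:
        row = self.table[(self.table.channel == channel) & (self.table.band == band)]
        if row.empty:
            raise KeyError(f"no entry for channel={channel!r}, band={band!r}")
        return float(row.erd_ers_percent.iloc[0])


def band_energy(segment: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Band energy (uV^2 * s) of a 1-D segment: band power x duration.

    The segment must span at least ``MIN_CYCLES`` cycles of the band's lower
    edge, otherwise the periodogram cannot resolve the band.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("band_energy expects a 1-D segment")
    f_lo, f_hi = band
    duration = segment.size / fs
    if f_lo > 0 and duration < MIN_CYCLES / f_lo:
        raise ValueError(
            f"window of {duration:.3f} s spans fewer than {MIN_CYCLES} cycles "
            f"of {f_lo} Hz; use a longer window"
        )
    psd = periodogram(segment, fs)
    return band_power(psd, f_lo, f_hi) * duration


def erd_ers_percent(E: float, R: float) -> float:
    """100 * (E - R) / R; negative = ERD, positive = ERS."""
    if E < 0:
        raise ValueError("event energy E must be >= 0")
    if R <= 0:
        raise ValueError(
            f"reference energy R must be positive, got {R}; "
            "ERD/ERS is undefined for an empty reference"
        )
    return 100.0 * (E - R) / R


def window_slice(window: tuple[float, float], cue_index: int, fs: float, n_samples: int) -> slice:
    """Half-open sample slice for a [a, b) second window relative to the cue."""
    a, b = window
    lo = cue_index + int(np.round(a * fs))
    hi = cue_index + int(np.round(b * fs))
    if lo >= hi:
        raise ValueError(f"degenerate window {window}")
    if lo < 0 or hi > n_samples:
        raise ValueError(
            f"window {window} s maps to samples [{lo}, {hi}) outside the trial"
        )
    return slice(lo, hi)


def erd_ers_map(
    es: EpochSet,
    label: str,
    channels: tuple[str, ...] = ("C3", "C4"),
    ref_window: tuple[float, float] = DEFAULT_REF_WINDOW,
    event_window: tuple[float, float] = DEFAULT_EVENT_WINDOW,
    bands: dict[str, tuple[float, float]] | None = None,
    min_trials: int = 10,
) -> ErdErsResult:
    """Trial-averaged ERD/ERS map for one class over selected channels.

    E and R are averaged across trials of the requested class before the
    ratio is taken.  Because the reference and event windows may differ in
    length, each window's band energy is divided by its duration (i.e. E
    and R enter the ratio as time-averaged band power, uV^2), which makes
    the percentage invariant to the window lengths.
    """
    bands = bands or DEFAULT_BANDS
    sub = es.select_label(label)
    if sub.n_trials == 0:
        raise ValueError(f"no trials with label {label!r}")
    if sub.n_trials < min_trials:
        raise ValueError(
            f"only {sub.n_trials} {label!r} trials; need >= {min_trials} "
            "for a stable trial-averaged estimate"
        )
    sl_ref = window_slice(ref_window, sub.cue_index, sub.fs, sub.n_samples)
    sl_ev = window_slice(event_window, sub.cue_index, sub.fs, sub.n_samples)
    dur_ref = (sl_ref.stop - sl_ref.start) / sub.fs
    dur_ev = (sl_ev.stop - sl_ev.start) / sub.fs

    rows = []
    for ch_name in channels:
        ch = sub.channel_index(ch_name)
        for band_name, band in bands.items():
            E = float(np.mean([
                band_energy(sub.data[i, ch, sl_ev], band, sub.fs)
                for i in range(sub.n_trials)
            ])) / dur_ev
            R = float(np.mean([
                band_energy(sub.data[i, ch, sl_ref], band, sub.fs)
                for i in range(sub.n_trials)
            ])) / dur_ref
            rows.append({
                "channel": ch_name, "band": band_name,
                "f_lo": band[0], "f_hi": band[1],
                "E": E, "R": R,
                "erd_ers_percent": erd_ers_percent(E, R),
            })
    return ErdErsResult(
        table=pd.DataFrame(rows),
        ref_window=tuple(ref_window),
        event_window=tuple(event_window),
        label=label,
        n_trials=sub.n_trials,
    )
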