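"""Periodogram power spectral density and band power.

The PSD estimator is the plain one-sided periodogram
``P[k] = |DFT(x)[k]|^2 / (N * fs)`` (interior bins doubled), so Parseval's
identity holds exactly: ``sum(P) * df`` equals the mean square of the
signal.  Band powers integrate the PSD over half-open frequency intervals
``[f_lo, f_hi)`` with the rectangle rule; an upper edge at (or beyond)
Nyquist includes the Nyquist bin so that bands tiling ``[0, fs/2]`` add up
to the total power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class PSDResult:
    """One-sided PSD on the grid ``0 .. fs/2`` with spacing ``fs/N``."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # uV^2/Hz
    n_samples: int
    fs: float

    @property
    def df(self) -> float:
        return self.fs / self.n_samples

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


def periodogram(
    x: np.ndarray,
    fs: float,
    *,
    average: bool = False,
    nperseg: int | None = None,
) -> PSDResult:
    """One-sided periodogram of a 1-D signal.

    With ``average=True`` the estimate is segment-averaged (Welch with
    non-overlapping boxcar segments of ``nperseg`` samples) to trade
    resolution for variance; the default is the raw periodogram.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("periodogram expects a 1-D signal")
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if fs <= 0:
        raise ValueError("fs must be positive")

    if average:
        nperseg = nperseg or max(2, x.size // 8)
        freqs, psd = sps.welch(
            x, fs=fs, window="boxcar", nperseg=nperseg, noverlap=0,
            detrend=False, scaling="density",
        )
        n_eff = nperseg
    else:
        freqs, psd = sps.periodogram(
            x, fs=fs, window="boxcar", detrend=False, scaling="density"
        )
        n_eff = x.size
    return PSDResult(freqs=freqs, psd=psd, n_samples=n_eff, fs=float(fs))


def band_power(psd: PSDResult, f_lo: float, f_hi: float) -> float:
    """Integrated power (uV^2) over the half-open band ``[f_lo, f_hi)``.

    ``f_hi >= fs/2`` additionally includes the Nyquist bin, so the full
    band ``[0, fs/2]`` recovers the signal's mean square (Parseval).
    """
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"band [{f_lo}, {f_hi}) must satisfy 0 <= f_lo < f_hi")
    if f_hi > psd.nyquist + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz exceeds Nyquist {psd.nyquist} Hz")
    mask = (psd.freqs >= f_lo) & (psd.freqs < f_hi)
    if f_hi >= psd.nyquist:
        mask |= np.isclose(psd.freqs, psd.nyquist)
    return float(np.sum(psd.psd[mask]) * psd.df)


def epoch_psd(data: np.ndarray, fs: float, *, average_trials: bool = True):
    """PSD of ``[trial, sample]`` (or 1-D) data for one channel.

    Convenience used by the CLI / analysis drivers: per-trial periodograms,
    optionally averaged across trials.
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    results = [periodogram(tr, fs) for tr in arr]
    freqs = results[0].freqs
    stack = np.stack([r.psd for r in results])
    psd = stack.mean(axis=0) if average_trials else stack
    return PSDResult(freqs=freqs, psd=psd, n_samples=arr.shape[1], fs=float(fs))
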