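"""Daubechies-6 wavelet band decomposition and selective reconstruction.

A 3-level Mallat-pyramid DWT with the 12-tap db6 filter pair splits a
100 Hz EEG signal into dyadic bands D1 = [25, 50), D2 = [12.5, 25),
D3 = [6.25, 12.5) and A3 = [0, 6.25) Hz.  Denoising keeps only the beta
(D2) and mu/alpha (D3) bands — the sensorimotor range — and reconstructs
the signal with D1 and A3 coefficients zeroed, removing high-frequency
noise and slow drifts/artifacts in one step.

The transform itself is computed with PyWavelets; this module owns the
band bookkeeping, the keep/zero reconstruction policy, and a hardcoded
copy of the db6 filter table that is checked for orthogonality at import
(so results cannot silently depend on a library's filter convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .core import EpochSet, config_hash

# 12-tap db6 scaling (lowpass analysis) filter, standard Daubechies table,
# in PyWavelets dec_lo ordering.
DB6_DEC_LO = np.array([
    -0.00107730108530848, 0.00477725751094551, 0.00055384220116150,
    -0.03158203931748603, 0.02752286553030573, 0.09750160558732304,
    -0.12976686756726194, -0.22626469396543983, 0.31525035170919763,
    0.75113390802109540, 0.49462389039845306, 0.11154074335010947,
])
# Quadrature-mirror highpass: dec_hi[k] = (-1)^(k+1) * dec_lo[L-1-k]
# (the sign convention shared by PyWavelets; the opposite global sign is
# equally orthogonal but would flip detail coefficients)
DB6_DEC_HI = np.array(
    [(-1.0) ** (k + 1) * DB6_DEC_LO[len(DB6_DEC_LO) - 1 - k]
     for k in range(len(DB6_DEC_LO))]
)


def _check_orthogonality() -> None:
    h = DB6_DEC_LO
    if abs(h.sum() - np.sqrt(2.0)) > 1e-12:
        raise AssertionError("db6 lowpass does not sum to sqrt(2)")
    for shift in range(0, len(h) // 2):
        ip = np.dot(h[: len(h) - 2 * shift], h[2 * shift:])
        want = 1.0 if shift == 0 else 0.0
        if abs(ip - want) > 1e-12:
            raise AssertionError(f"db6 double-shift orthogonality fails at {shift}")


_check_orthogonality()

_PYWT_MODE = {"symmetric": "symmetric", "periodic": "periodization"}


@dataclass
class WaveletSpec:
    """db6 Mallat-pyramid specification.

    ``boundary='symmetric'`` uses symmetric signal extension (default,
    minimal edge artifacts on short epochs); ``'periodic'`` uses periodized
    coefficients (exact energy conservation, ceil(L/2) coefficients per
    level).
    """

    family: str = "db6"
    n_levels: int = 3
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.family != "db6":
            raise ValueError("only the db6 family is supported")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.boundary not in _PYWT_MODE:
            raise ValueError(f"boundary must be one of {sorted(_PYWT_MODE)}")

    @property
    def filter_length(self) -> int:
        return len(DB6_DEC_LO)

    def min_signal_length(self) -> int:
        # deepest level must still see a full filter support
        return (self.filter_length - 1) * 2 ** (self.n_levels - 1)


def band_map(fs: float, n_levels: int) -> dict[str, tuple[float, float]]:
    """Exact dyadic (f_lo, f_hi) in Hz per band; bands tile [0, fs/2)."""
    bands = {
        f"D{l}": (fs / 2 ** (l + 1), fs / 2**l) for l in range(1, n_levels + 1)
    }
    bands[f"A{n_levels}"] = (0.0, fs / 2 ** (n_levels + 1))
    return bands


@dataclass
class BandDecomposition:
    """Per-level detail/approximation coefficients plus their band map."""

    details: list[np.ndarray]  # D1 .. Dn
    approx: np.ndarray  # An
    band_map: dict[str, tuple[float, float]]
    fs: float
    original_length: int
    spec: WaveletSpec = field(default_factory=WaveletSpec)

    @property
    def band_names(self) -> list[str]:
        return [f"D{l}" for l in range(1, len(self.details) + 1)] + [
            f"A{len(self.details)}"
        ]

    def coefficients(self, name: str) -> np.ndarray:
        if name == f"A{len(self.details)}":
            return self.approx
        if name.startswith("D"):
            lvl = int(name[1:])
            if 1 <= lvl <= len(self.details):
                return self.details[lvl - 1]
        raise KeyError(f"unknown band {name!r}; have {self.band_names}")

    def energy(self) -> float:
        return float(
            sum(np.sum(d**2) for d in self.details) + np.sum(self.approx**2)
        )


def dwt(x: np.ndarray, spec: WaveletSpec | None = None, fs: float = 100.0) -> BandDecomposition:
    """Mallat-pyramid analysis: cascade of convolve-and-downsample stages."""
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if x.size < spec.min_signal_length():
        raise ValueError(
            f"signal length {x.size} below minimum {spec.min_signal_length()} "
            f"for {spec.n_levels} db6 levels"
        )
    coeffs = pywt.wavedec(
        x, "db6", mode=_PYWT_MODE[spec.boundary], level=spec.n_levels
    )
    approx, details_deep_first = coeffs[0], coeffs[1:]
    details = list(details_deep_first[::-1])  # reorder to D1..Dn
    return BandDecomposition(
        details=details,
        approx=approx,
        band_map=band_map(fs, spec.n_levels),
        fs=float(fs),
        original_length=x.size,
        spec=spec,
    )


def reconstruct(decomp: BandDecomposition, keep: set[str] | None = None) -> np.ndarray:
    """Inverse pyramid after zeroing all bands not in ``keep``.

    ``keep=None`` keeps every band (perfect reconstruction).  Output length
    equals the analysed signal's length.
    """
    names = decomp.band_names
    if keep is None:
        keep = set(names)
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty; nothing to reconstruct")
    unknown = keep - set(names)
    if unknown:
        raise KeyError(f"unknown bands {sorted(unknown)}; have {names}")

    n = len(decomp.details)
    approx = decomp.approx if f"A{n}" in keep else np.zeros_like(decomp.approx)
    details_deep_first = [
        decomp.details[l - 1] if f"D{l}" in keep else np.zeros_like(decomp.details[l - 1])
        for l in range(n, 0, -1)
    ]
    y = pywt.waverec(
        [approx, *details_deep_first], "db6", mode=_PYWT_MODE[decomp.spec.boundary]
    )
    return y[: decomp.original_length]


def resample_to(es: EpochSet, fs_new: float) -> EpochSet:
    """Polyphase (anti-aliased) resampling of every trial/channel.

    Used to bring 250 Hz acquisitions onto the 100 Hz grid the 3-level band
    scheme is defined for.
    """
    if fs_new <= 0:
        raise ValueError("fs_new must be positive")
    if fs_new == es.fs:
        return es
    frac = Fraction(fs_new / es.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(es.data, up, down, axis=2)
    cue = int(round(es.cue_index * fs_new / es.fs))
    prov = dict(es.provenance)
    prov["resampled_from_hz"] = es.fs
    return EpochSet(
        data=data, labels=es.labels, fs=float(fs_new),
        channel_names=list(es.channel_names), cue_index=cue, provenance=prov,
    )


def preprocess_epochs(
    es: EpochSet,
    spec: WaveletSpec | None = None,
    keep: tuple[str, ...] = ("D2", "D3"),
    resample: bool = False,
) -> EpochSet:
    """Wavelet denoising of every trial/channel: keep D2+D3, zero D1+A3.

    The 3-level band semantics (D2 = beta 12.5-25 Hz, D3 = mu 6.25-12.5 Hz)
    hold at 100 Hz only; other sampling rates must be resampled first
    (``resample=True`` does it in place via :func:`resample_to`).
    """
    spec = spec or WaveletSpec()
    if es.fs != 100.0:
        if resample:
            es = resample_to(es, 100.0)
        else:
            raise ValueError(
                f"band scheme is defined at fs=100 Hz, got {es.fs}; "
                "resample first (resample=True or resample_to(es, 100))"
            )
    out = np.empty_like(es.data)
    keep_set = set(keep)
    for i in range(es.n_trials):
        for c in range(es.n_channels):
            decomp = dwt(es.data[i, c], spec, es.fs)
            out[i, c] = reconstruct(decomp, keep_set)
    prov = dict(es.provenance)
    prov["wavelet"] = {
        "family": spec.family, "n_levels": spec.n_levels,
        "boundary": spec.boundary, "keep": sorted(keep_set),
        "spec_hash": config_hash(spec),
    }
    return EpochSet(
        data=out, labels=es.labels, fs=es.fs,
        channel_names=list(es.channel_names), cue_index=es.cue_index,
        provenance=prov,
    )
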