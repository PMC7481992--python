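"""EEG conditioning and multitaper spectral decomposition.

The EEG path of the pipeline is: resample to 500 Hz, linear detrend,
band-limit to 0.5–45 Hz (:func:`condition_eeg`); regress out the EOG channels
(:func:`regress_out_eog`); estimate per-channel power spectral density with
DPSS multitapers and integrate it over the canonical frequency bands
(:func:`multitaper_band_power`); average relative power over the three
channels of each (hemisphere, area) group (:func:`area_band_power`).

Band definitions default to contiguous half-open intervals
delta [1, 4), theta [4, 8), alpha [8, 13), beta [13, 30) Hz.  Relative power
is band power divided by total power over 0.5–45 Hz, so the four bands sum to
at most 1 per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigError, DataError
from .montage import AREAS, HEMISPHERES, NodeScheme

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BandPowerTable",
    "condition_eeg",
    "regress_out_eog",
    "multitaper_psd",
    "multitaper_band_power",
    "area_band_power",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"band {self.name!r}: need lo < hi, got [{self.lo}, {self.hi})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

#: Total-power integration range (Hz) for relative power.
TOTAL_RANGE: tuple[float, float] = (0.5, 45.0)


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise DataError(f"{what} contains non-finite samples")


def condition_eeg(
    raw: np.ndarray,
    fs_in: float,
    fs_out: float = 500.0,
    passband: tuple[float, float] = (0.5, 45.0),
) -> np.ndarray:
    """Resample to ``fs_out``, linearly detrend, and band-limit each channel.

    Parameters
    ----------
    raw
        ``(channels, samples)`` array.
    fs_in
        Input sampling rate (Hz); must exceed 60 Hz with at least 2 s of data.
    fs_out
        Target rate, 500 Hz by default.
    passband
        Butterworth band-pass corner frequencies (Hz), zero-phase applied.

    Notes
    -----
    Zero-padding to the next power of two happens inside the spectral
    estimator (``nfft``), not here, so EEG and EOG stay sample-aligned for
    the ocular-artifact regression.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs_in <= 60:
        raise DataError(f"input sampling rate must exceed 60 Hz, got {fs_in}")
    if raw.shape[1] < 2 * fs_in:
        raise DataError(
            f"need at least 2 s of data ({int(2 * fs_in)} samples at {fs_in} Hz), "
            f"got {raw.shape[1]}"
        )
    _check_finite(raw, "EEG")

    if fs_in != fs_out:
        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        x = signal.resample_poly(raw, frac.numerator, frac.denominator, axis=1)
    else:
        x = raw.copy()

    x = signal.detrend(x, axis=1, type="linear")

    lo, hi = passband
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs_out, output="sos")
    return signal.sosfiltfilt(sos, x, axis=1)


def regress_out_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Remove ocular artifacts by per-channel OLS regression on the EOG.

    Each EEG channel is replaced by its residual after least-squares
    projection (with intercept) onto the EOG channel subspace; residuals are
    uncorrelated with every retained EOG channel.  Constant (zero-variance)
    EOG channels are dropped with a warning.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eeg.shape[1] != eog.shape[1]:
        raise DataError(
            f"EEG and EOG sample counts differ ({eeg.shape[1]} vs {eog.shape[1]})"
        )
    _check_finite(eeg, "EEG")
    _check_finite(eog, "EOG")

    keep = eog.std(axis=1) > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant EOG channel(s) from the regression",
            stacklevel=2,
        )
    eog = eog[keep]
    if eog.shape[0] == 0:
        return eeg - eeg.mean(axis=1, keepdims=True)

    design = np.column_stack([np.ones(eeg.shape[1]), eog.T])
    beta, *_ = np.linalg.lstsq(design, eeg.T, rcond=None)
    return eeg - (design @ beta).T


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    nw: float = 4.0,
    n_tapers: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue-weighted DPSS multitaper PSD estimate.

    Parameters
    ----------
    x
        ``(channels, samples)`` conditioned signal.
    fs
        Sampling rate in Hz.
    nw
        Time-bandwidth product (half-bandwidth W = nw/T Hz).
    n_tapers
        Number of DPSS tapers; defaults to ``2*nw - 1``.

    Returns
    -------
    freqs, psd
        One-sided frequency grid (Hz) and ``(channels, freqs)`` PSD in
        signal-units²/Hz, zero-padded to the next power-of-two length.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    if n < 2 * fs:
        raise DataError(f"need at least 2 s of signal for the PSD, got {n} samples")
    if n_tapers is None:
        n_tapers = int(2 * nw - 1)
    tapers, eigvals = signal.windows.dpss(n, nw, Kmax=n_tapers, return_ratios=True)

    nfft = _next_pow2(n)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    # (tapers, channels, freqs) tapered periodograms
    spec = np.fft.rfft(tapers[:, None, :] * x[None, :, :], n=nfft, axis=-1)
    pxx = (np.abs(spec) ** 2) / fs
    # one-sided: double everything except DC and Nyquist
    pxx[..., 1:] *= 2.0
    if nfft % 2 == 0:
        pxx[..., -1] /= 2.0
    weights = eigvals / eigvals.sum()
    return freqs, np.tensordot(weights, pxx, axes=(0, 0))


@dataclass
class BandPowerTable:
    """Per-channel absolute and relative band power.

    Attributes
    ----------
    bands
        Band definitions, in table column order.
    absolute
        ``(channels, bands)`` band-integrated PSD (units²).
    relative
        ``(channels, bands)`` band power / total power over 0.5–45 Hz; each
        value in [0, 1] and the per-channel row sum is at most 1.
    total_power
        ``(channels,)`` integral of the PSD over 0.5–45 Hz.
    """

    bands: tuple[BandDefinition, ...]
    absolute: np.ndarray
    relative: np.ndarray
    total_power: np.ndarray

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def to_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        """Tidy table: one row per (channel, band)."""
        rows = []
        for i, label in enumerate(labels):
            for j, b in enumerate(self.bands):
                rows.append(
                    {
                        "channel": label,
                        "band": b.name,
                        "relative_power": self.relative[i, j],
                        "absolute_power": self.absolute[i, j],
                        "total_power": self.total_power[i],
                    }
                )
        return pd.DataFrame(rows)


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (freqs >= lo) & (freqs < hi)
    if mask.sum() < 2:
        raise ConfigError(f"band [{lo}, {hi}) covers fewer than 2 frequency bins")
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def multitaper_band_power(
    x: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    nw: float = 4.0,
    n_tapers: Optional[int] = None,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> BandPowerTable:
    """Integrate the multitaper PSD over frequency bands.

    Relative power is the band integral divided by the integral over
    ``total_range`` (0.5–45 Hz by default).
    """
    nyq = fs / 2.0
    for b in bands:
        if b.hi > nyq:
            raise ConfigError(f"band {b.name!r} upper edge {b.hi} Hz exceeds Nyquist {nyq} Hz")
    freqs, psd = multitaper_psd(x, fs, nw=nw, n_tapers=n_tapers)
    total = _band_integral(freqs, psd, *total_range)
    absolute = np.column_stack([_band_integral(freqs, psd, b.lo, b.hi) for b in bands])
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = absolute / total[:, None]
    relative = np.where(total[:, None] > 0, relative, 0.0)
    return BandPowerTable(tuple(bands), absolute, relative, total)


def area_band_power(table: BandPowerTable, scheme: NodeScheme) -> pd.DataFrame:
    """Average relative power over each (hemisphere, area) channel group.

    Returns a DataFrame indexed by ``(hemisphere, area)`` with one column per
    band.  Channel row order must match the scheme's node order.
    """
    if table.relative.shape[0] != len(scheme):
        raise DataError(
            f"band power table has {table.relative.shape[0]} channels but scheme "
            f"{scheme.name!r} has {len(scheme)} nodes"
        )
    index = pd.MultiIndex.from_product(
        [HEMISPHERES, scheme.areas_present()], names=["hemisphere", "area"]
    )
    out = pd.DataFrame(index=index, columns=table.band_names, dtype=float)
    for hemi in HEMISPHERES:
        for area in scheme.areas_present():
            mask = scheme.area_mask(hemi, area)
            out.loc[(hemi, area)] = table.relative[mask].mean(axis=0)
    return out
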