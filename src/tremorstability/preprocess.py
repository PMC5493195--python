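"""Signal conditioning: trend correction, dominant-axis extraction,
peak-frequency identification and tremor-band filtering.

All filters are third-order Butterworth applied forward and backward
(zero net phase) with odd-symmetric edge extension.  The conditioning chain
for a triaxial recording is::

    0.1 Hz high-pass detrend  ->  PCA (first principal component)
        ->  peak frequency f_c in 2-9 Hz  ->  band-pass (f_c-2, f_c+2) Hz

Uniaxial (laser) recordings skip the PCA stage.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import DEFAULT_CONFIG, AnalysisConfig
from .exceptions import ConfigurationError, DataError
from .io import Recording, UniaxialRecording


class AxisProvenance(str, enum.Enum):
    PC1 = "pc1"
    NATIVE_UNIAXIAL = "native_uniaxial"


@dataclass(frozen=True)
class TremorAxisSignal:
    """One-dimensional tremor signal with its provenance and band history."""

    values: np.ndarray
    fs: float
    provenance: AxisProvenance
    band: Optional[tuple] = None  # (low_hz, high_hz) applied so far
    units: Optional[object] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise DataError("axis signal must be a vector of length >= 2")
        if self.band is not None and not self.band[0] < self.band[1]:
            raise ConfigurationError(f"invalid band {self.band}")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class PeakBand:
    """Peak tremor frequency f_c and the band (f_c - 2, f_c + 2) around it."""

    f_c: float
    search_range: tuple = (2.0, 9.0)
    halfwidth: float = 2.0

    def __post_init__(self):
        lo, hi = self.search_range
        if not lo <= self.f_c <= hi:
            raise ConfigurationError(
                f"f_c={self.f_c} outside search range {self.search_range}"
            )

    @property
    def band(self) -> tuple:
        return (self.f_c - self.halfwidth, self.f_c + self.halfwidth)


def _pad_length(order: int) -> int:
    # odd-symmetric extension, 3 x (2*order + 1) samples per end
    return 3 * (2 * order + 1)


def _filtfilt(values: np.ndarray, corner_hz: float, btype: str, fs: float, order: int) -> np.ndarray:
    padlen = _pad_length(order)
    if values.shape[-1] <= padlen:
        raise DataError(
            f"signal too short for stable zero-phase filtering "
            f"(need > {padlen} samples, got {values.shape[-1]})"
        )
    if not corner_hz < fs / 2:
        raise ConfigurationError(
            f"corner {corner_hz} Hz is not below Nyquist ({fs / 2} Hz)"
        )
    sos = sps.butter(order, corner_hz, btype=btype, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, values, padtype="odd", padlen=padlen)


def highpass_detrend(rec: Recording, config: AnalysisConfig = DEFAULT_CONFIG) -> Recording:
    """Remove slow drift with a zero-phase high-pass (0.1 Hz corner).

    Each axis is filtered independently; the forward-backward application
    squares the Butterworth magnitude response and cancels the phase.
    """
    filtered = _filtfilt(
        rec.samples, config.detrend_corner_hz, "highpass", rec.fs, config.filter_order
    )
    return dataclasses.replace(rec, samples=filtered)


def principal_axis(rec: Recording) -> TremorAxisSignal:
    """Project a triaxial recording onto its dominant tremor axis.

    The projection is onto the eigenvector of the sample covariance with the
    largest eigenvalue, after mean-centring each axis — equivalent to a
    virtual rotation of the sensor.  The eigenvector's sign is mathematically
    arbitrary; it is canonicalised so the projected signal has non-negative
    third central moment, which makes the output (and everything downstream)
    invariant to rotations of the sensor frame.  Uniaxial recordings pass
    through unchanged (provenance ``native_uniaxial``).
    """
    if isinstance(rec, UniaxialRecording):
        return TremorAxisSignal(
            values=rec.samples - rec.samples.mean(),
            fs=rec.fs,
            provenance=AxisProvenance.NATIVE_UNIAXIAL,
            units=rec.units,
        )
    if rec.n_samples < 3:
        raise DataError("need at least 3 samples for a covariance estimate")
    centred = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    cov = centred @ centred.T / (rec.n_samples - 1)
    if not np.trace(cov) > 0:
        raise DataError("degenerate covariance: recording has zero variance")
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1 = eigvecs[:, np.argmax(eigvals)]
    values = pc1 @ centred
    if np.mean(values**3) < 0:  # frame-invariant sign convention
        values = -values
    return TremorAxisSignal(
        values=values,
        fs=rec.fs,
        provenance=AxisProvenance.PC1,
        units=rec.units,
    )


def welch_spectrum(sig: TremorAxisSignal, config: AnalysisConfig = DEFAULT_CONFIG):
    """Welch power spectral density (Hann window, 50% overlap)."""
    nperseg = min(int(round(config.welch_segment_s * sig.fs)), sig.n_samples)
    return sps.welch(
        sig.values, fs=sig.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )


def peak_frequency(sig: TremorAxisSignal, config: AnalysisConfig = DEFAULT_CONFIG) -> PeakBand:
    """Locate the peak tremor frequency f_c within the 2-9 Hz search range.

    Uses the Welch periodogram with parabolic interpolation of the peak bin,
    so f_c is not quantised to the bin grid.
    """
    lo, hi = config.peak_search_hz
    if sig.duration_s < 4.0:
        raise DataError(
            f"need >= 4 s of signal to resolve the tremor peak, got {sig.duration_s:.2f} s"
        )
    if sig.fs < 2 * hi:
        raise DataError(f"fs={sig.fs} Hz cannot represent the {hi} Hz search limit")
    freqs, power = welch_spectrum(sig, config)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise DataError("no spectral estimate inside the search range")
    idx = np.flatnonzero(mask)
    peak = idx[np.argmax(power[idx])]
    f_c = freqs[peak]
    if 0 < peak < len(freqs) - 1:
        y0, y1, y2 = power[peak - 1 : peak + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper local maximum
            delta = 0.5 * (y0 - y2) / denom
            f_c = freqs[peak] + delta * (freqs[1] - freqs[0])
    f_c = float(np.clip(f_c, lo, hi))
    return PeakBand(f_c=f_c, search_range=(lo, hi), halfwidth=config.band_halfwidth_hz)


def bandpass_tremor(
    sig: TremorAxisSignal, band: PeakBand, config: AnalysisConfig = DEFAULT_CONFIG
) -> TremorAxisSignal:
    """Restrict the signal to the tremor band (f_c - 2, f_c + 2) Hz.

    Separate zero-phase third-order Butterworth high- and low-pass stages.
    When f_c - 2 falls at or below the detrend corner the high-pass stage is
    skipped: the 0.1 Hz detrend already removed everything below it and a
    near-zero corner is numerically meaningless.
    """
    low, high = band.band
    if high >= sig.fs / 2:
        raise ConfigurationError(
            f"band upper edge {high} Hz is not below Nyquist ({sig.fs / 2} Hz)"
        )
    values = sig.values
    if low > config.detrend_corner_hz:
        values = _filtfilt(values, low, "highpass", sig.fs, config.filter_order)
    values = _filtfilt(values, high, "lowpass", sig.fs, config.filter_order)
    return dataclasses.replace(sig, values=values, band=(max(low, 0.0), high))


def butterworth_gain(f_hz, corner_hz: float, order: int = 3, btype: str = "highpass"):
    """Analytic forward-backward Butterworth amplitude gain at ``f_hz``.

    |H(f)|^2 of the analogue prototype; the squared (zero-phase) response.
    Useful as an independent oracle for the time-domain filters.
    """
    ratio = np.asarray(f_hz, dtype=float) / corner_hz
    mag2 = ratio ** (2 * order) / (1.0 + ratio ** (2 * order))
    if btype == "lowpass":
        mag2 = 1.0 / (1.0 + ratio ** (2 * order))
    return mag2  # forward-backward amplitude gain = |H|^2
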