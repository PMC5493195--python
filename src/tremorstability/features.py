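"""Cycle-by-cycle tremor analysis and per-recording scalar features.

The central quantity is the tremor stability index (TSI): positive-gradient
zero-crossings of the band-passed tremor signal define cycle boundaries,
instantaneous frequencies are the reciprocals of the inter-crossing
intervals, f_n = 1/T_n, their consecutive differences form the series
Δf_n = f_n − f_{n+1}, and

    TSI = IQR(Δf)   [Hz]

A stable (Parkinsonian rest) tremor produces a narrow Δf distribution and a
small TSI; essential tremor wanders cycle to cycle and produces a wide one.

Also computed here: the comparator frequency-variability statistics
(mean frequency, F_SD, F_cov, Δf_SD, Δf_cov), the smoothed Hilbert amplitude
envelope, a band-power signal-to-noise ratio, and the mean harmonic power
(MHP) — the log of the mean spectral power at the tremor peak and its first
three higher harmonics, computed on acceleration in milligravities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .config import DEFAULT_CONFIG, AnalysisConfig
from .exceptions import ConfigurationError, DataError
from .io import Recording, Units, convert_units
from .preprocess import (
    PeakBand,
    TremorAxisSignal,
    bandpass_tremor,
    highpass_detrend,
    peak_frequency,
    principal_axis,
    welch_spectrum,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# zero crossings and cycle series


def zero_crossings(
    sig: TremorAxisSignal, config: AnalysisConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Times (s) of positive-gradient zero crossings of the band-passed signal.

    Each crossing is refined by linear interpolation between the bracketing
    samples, decoupling crossing times from the sampling grid.  The first and
    last ``edge_margin_s`` seconds are excluded as filter-edge-affected.
    """
    x = sig.values
    neg = x < 0
    idx = np.flatnonzero(neg[:-1] & ~neg[1:])
    if idx.size == 0:
        raise DataError("no positive-gradient zero crossings in signal")
    frac = -x[idx] / (x[idx + 1] - x[idx])
    times = (idx + frac) / sig.fs
    margin = config.edge_margin_s
    times = times[(times >= margin) & (times <= sig.duration_s - margin)]
    if times.size < 3:
        raise DataError(
            f"only {times.size} zero crossings away from edges; "
            "cannot form a delta-f series"
        )
    return times


@dataclass(frozen=True)
class CycleSeries:
    """Per-cycle decomposition of a tremor signal.

    ``crossing_times`` are the retained positive-gradient zero crossings,
    ``freqs`` the instantaneous frequencies f_n = 1/T_n of plausible cycles,
    ``delta_f`` the consecutive differences Δf_n = f_n − f_{n+1} (formed only
    between cycles that are adjacent in time), and ``amplitudes`` the
    smoothed Hilbert envelope sampled at each crossing.
    """

    crossing_times: np.ndarray
    intervals: np.ndarray        # all inter-crossing intervals T_n (s)
    freqs: np.ndarray            # plausible f_n (Hz)
    delta_f: np.ndarray          # Δf between adjacent plausible cycles (Hz)
    amplitudes: Optional[np.ndarray] = None
    n_merged: int = 0            # implausibly short intervals merged
    n_dropped: int = 0           # implausibly long intervals excluded

    @property
    def n_cycles(self) -> int:
        return self.freqs.size

    def window_delta_f(self, start_s: float, stop_s: float) -> np.ndarray:
        """Δf series restricted to crossings inside ``[start_s, stop_s]``.

        Used to recompute the TSI on a sub-segment without re-running the
        filtering chain (the crossing times are segment-independent away
        from filter edges).
        """
        t = self.crossing_times
        sel = t[(t >= start_s) & (t <= stop_s)]
        if sel.size < 3:
            return np.empty(0)
        f = 1.0 / np.diff(sel)
        return f[:-1] - f[1:]


def cycle_series(
    crossing_times: Sequence[float],
    envelope: Optional[np.ndarray] = None,
    fs: Optional[float] = None,
    plausible_range: Optional[tuple] = None,
) -> CycleSeries:
    """Build the cycle series (T_n, f_n, Δf_n, a_n) from crossing times.

    ``plausible_range`` (Hz) guards against numerical edge artefacts: an
    interval implying a frequency above the range is merged with the
    following interval; one below the range (a missed cycle) is excluded,
    and Δf is never formed across the gap.  Both events are logged.
    """
    times = np.asarray(crossing_times, dtype=float)
    if times.size < 3:
        raise DataError("need at least 3 crossings to form a delta-f series")
    if np.any(np.diff(times) <= 0):
        raise DataError("crossing times must be strictly increasing")

    n_merged = 0
    if plausible_range is not None:
        hi = plausible_range[1]
        while times.size >= 3:
            f = 1.0 / np.diff(times)
            bad = np.flatnonzero(f > hi)
            if bad.size == 0:
                break
            # merge the offending interval with the one that follows it
            drop = min(bad[0] + 1, times.size - 2)
            times = np.delete(times, drop)
            n_merged += 1
        if times.size < 3:
            raise DataError("too few plausible cycles after merging")

    intervals = np.diff(times)
    f_all = 1.0 / intervals
    if plausible_range is not None:
        valid = f_all >= plausible_range[0]
    else:
        valid = np.ones_like(f_all, dtype=bool)
    n_dropped = int((~valid).sum())
    if n_merged or n_dropped:
        logger.info("cycle guard: merged %d, dropped %d intervals", n_merged, n_dropped)

    freqs = f_all[valid]
    pair = valid[:-1] & valid[1:]
    delta_f = (f_all[:-1] - f_all[1:])[pair]

    amplitudes = None
    if envelope is not None:
        if fs is None:
            raise ConfigurationError("fs required to sample the envelope at crossings")
        t_axis = np.arange(len(envelope)) / fs
        amplitudes = np.interp(times, t_axis, envelope)

    return CycleSeries(
        crossing_times=times,
        intervals=intervals,
        freqs=freqs,
        delta_f=delta_f,
        amplitudes=amplitudes,
        n_merged=n_merged,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# scalar features


def tsi(cycles, min_count: int = 4, method: str = "linear") -> float:
    """Tremor stability index: interquartile range of Δf (Hz).

    Quantiles use linear interpolation between order statistics (the type-7
    rule), so values are reproducible bit-for-bit across runs and platforms.
    """
    delta_f = cycles.delta_f if isinstance(cycles, CycleSeries) else np.asarray(cycles, float)
    if delta_f.size < min_count:
        raise DataError(
            f"need at least {min_count} delta-f values for the TSI, got {delta_f.size}"
        )
    q1, q3 = np.percentile(delta_f, [25.0, 75.0], method=method)
    return float(q3 - q1)


def amplitude_envelope(
    sig: TremorAxisSignal, config: AnalysisConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal, smoothed by a centred
    moving average of ``smooth_window_s`` (default 1 s)."""
    env = np.abs(hilbert(sig.values))
    size = max(1, int(round(config.smooth_window_s * sig.fs)))
    if size % 2 == 0:
        size += 1  # keep the average centred
    return uniform_filter1d(env, size=size, mode="nearest")


def snr_db(
    filtered: TremorAxisSignal,
    unfiltered: TremorAxisSignal,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple:
    """Signal-to-noise ratio time series (dB) and its mean.

    20·log10 of the smoothed envelope of the band-passed signal over the
    envelope of the residual (unfiltered minus filtered).  The residual
    envelope is floored at 1e-12 of the median signal envelope so that
    noiseless inputs saturate at ``snr_cap_db`` instead of dividing by zero.
    Harmonics removed by the band-pass count towards the "noise" term.
    """
    if filtered.n_samples != unfiltered.n_samples or filtered.fs != unfiltered.fs:
        raise DataError("filtered and unfiltered signals must share length and fs")
    env_sig = amplitude_envelope(filtered, config)
    residual = TremorAxisSignal(
        values=unfiltered.values - filtered.values,
        fs=filtered.fs,
        provenance=filtered.provenance,
    )
    env_noise = amplitude_envelope(residual, config)
    floor = 1e-12 * max(np.median(env_sig), np.finfo(float).tiny)
    ratio = env_sig / np.maximum(env_noise, floor)
    with np.errstate(divide="ignore"):
        series = 20.0 * np.log10(np.maximum(ratio, 10 ** (-config.snr_cap_db / 20)))
    series = np.clip(series, -config.snr_cap_db, config.snr_cap_db)
    return series, float(series.mean())


@dataclass(frozen=True)
class VariabilityFeatures:
    mean_f: float
    f_sd: float
    f_cov: float
    df_sd: float
    df_cov: float


def variability_features(cycles: CycleSeries) -> VariabilityFeatures:
    """Comparator statistics of the f_n and Δf series.

    Sample standard deviations (n−1 denominator); coefficients of variation
    divide by |mean|.  Δf is near-symmetric about zero, so its mean can
    vanish — Δf_cov is then reported missing (NaN) rather than infinite.
    """
    f = cycles.freqs
    if f.size < 2:
        raise DataError("need at least 2 cycles for variability features")
    mean_f = float(f.mean())
    f_sd = float(f.std(ddof=1))
    f_cov = f_sd / abs(mean_f) if abs(mean_f) > 1e-12 else math.nan
    df = cycles.delta_f
    if df.size >= 2:
        df_sd = float(df.std(ddof=1))
        mean_df = float(df.mean())
        df_cov = df_sd / abs(mean_df) if abs(mean_df) > 1e-12 else math.nan
    else:
        df_sd = math.nan
        df_cov = math.nan
    return VariabilityFeatures(mean_f, f_sd, f_cov, df_sd, df_cov)


def mhp_from_harmonic_powers(powers, base: float = 10.0) -> float:
    """MHP = log of the mean of the spectral power at f_T, 2f_T, 3f_T, 4f_T."""
    powers = np.asarray(powers, dtype=float)
    if powers.size != 4 or np.any(powers < 0):
        raise ConfigurationError("MHP requires 4 non-negative harmonic powers")
    return float(np.log(powers.mean()) / np.log(base))


def mhp(
    sig: TremorAxisSignal,
    f_t: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Mean harmonic power of the tremor at peak frequency ``f_t``.

    The Welch power spectrum (same estimator settings as the peak search) is
    read at the bins nearest to k·f_T for k = 1..4.  The signal must already
    be expressed in milligravities for values comparable across devices.
    """
    if not 4 * f_t < sig.fs / 2:
        raise ConfigurationError(
            f"4·f_T = {4 * f_t} Hz reaches Nyquist ({sig.fs / 2} Hz)"
        )
    freqs, power = welch_spectrum(sig, config)
    bins = [int(np.argmin(np.abs(freqs - k * f_t))) for k in range(1, 5)]
    return mhp_from_harmonic_powers(power[bins], base=config.mhp_log_base)


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class ConditionedRecording:
    """Intermediate products of the conditioning chain, kept for reuse."""

    axis: TremorAxisSignal       # detrended dominant-axis signal (pre band-pass)
    peak: PeakBand
    banded: TremorAxisSignal     # band-passed tremor signal
    envelope: np.ndarray
    cycles: CycleSeries
    units: Units
    duration_s: float
    subject_id: str
    state: str


def condition_recording(
    rec: Recording, config: AnalysisConfig = DEFAULT_CONFIG
) -> ConditionedRecording:
    """Run detrend → (PCA) → peak search → band-pass → crossings once."""
    if rec.units.is_acceleration and rec.units != Units.MG:
        rec = convert_units(rec, Units.MG)
    detrended = highpass_detrend(rec, config)
    axis = principal_axis(detrended)
    peak = peak_frequency(axis, config)
    if rec.fs < 4 * (peak.f_c + config.band_halfwidth_hz):
        raise DataError(
            f"fs={rec.fs} Hz too low for reliable crossing detection at "
            f"f_c={peak.f_c:.2f} Hz (need >= {4 * (peak.f_c + config.band_halfwidth_hz)})"
        )
    banded = bandpass_tremor(axis, peak, config)
    envelope = amplitude_envelope(banded, config)
    crossings = zero_crossings(banded, config)
    lo, hi = peak.band
    plausible = (
        max(lo - config.plausibility_margin_hz, 0.05),
        hi + config.plausibility_margin_hz,
    )
    cycles = cycle_series(crossings, envelope=envelope, fs=banded.fs, plausible_range=plausible)
    return ConditionedRecording(
        axis=axis,
        peak=peak,
        banded=banded,
        envelope=envelope,
        cycles=cycles,
        units=rec.units,
        duration_s=rec.duration_s,
        subject_id=rec.subject_id,
        state=rec.state.value,
    )


@dataclass(frozen=True)
class FeatureRecord:
    """Per-recording scalar features."""

    subject_id: str
    state: str
    tsi: float          # Hz, IQR of Δf
    mean_f: float       # Hz
    f_sd: float         # Hz
    f_cov: float
    df_sd: float        # Hz
    df_cov: float
    mhp: float          # log10 power (mg^2-based); NaN for velocity input
    snr_db: float       # dB, mean over the recording
    n_cycles: int
    f_c: float          # Hz, spectral peak
    duration_s: float

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in FEATURE_COLUMNS}


FEATURE_COLUMNS = (
    "subject_id",
    "state",
    "tsi",
    "mean_f",
    "f_sd",
    "f_cov",
    "df_sd",
    "df_cov",
    "mhp",
    "snr_db",
    "n_cycles",
    "f_c",
    "duration_s",
)


def compute_features(
    rec: Recording, config: AnalysisConfig = DEFAULT_CONFIG
) -> FeatureRecord:
    """Full per-recording pipeline: conditioning chain plus every scalar feature.

    Deterministic for a fixed input and configuration.  MHP is reported
    missing for velocity recordings (the formula is defined on acceleration
    in mg) and when the fourth harmonic would exceed Nyquist.
    """
    cond = condition_recording(rec, config)
    cycles = cond.cycles
    tsi_val = tsi(cycles, method=config.quantile_rule)
    var = variability_features(cycles)
    _, snr_mean = snr_db(cond.banded, cond.axis, config)
    if cond.units.is_acceleration and 4 * cond.peak.f_c < cond.axis.fs / 2:
        mhp_val = mhp(cond.axis, cond.peak.f_c, config)
    else:
        mhp_val = math.nan
    return FeatureRecord(
        subject_id=cond.subject_id,
        state=cond.state,
        tsi=tsi_val,
        mean_f=var.mean_f,
        f_sd=var.f_sd,
        f_cov=var.f_cov,
        df_sd=var.df_sd,
        df_cov=var.df_cov,
        mhp=mhp_val,
        snr_db=snr_mean,
        n_cycles=cycles.n_cycles,
        f_c=cond.peak.f_c,
        duration_s=cond.duration_s,
    )


def feature_table(pairs, config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One row per (recording, label) pair; columns per FEATURE_COLUMNS + label."""
    rows = []
    for rec, label in pairs:
        record = compute_features(rec, config).to_dict()
        record["label"] = label
        rows.append(record)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + ["label"])
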