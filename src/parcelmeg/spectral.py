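"""Parcel time-course conditioning, Welch spectra and canonical band power.

Conditioning mirrors standard offline resting-state practice: mains notch at
50/100 Hz, polyphase resampling to 250 Hz, automated bad-segment excision by
a robust log-variance rule, and a final 1-80 Hz band-pass.  Spectra are
Welch periodograms with a 2-s Hann window (0.5 Hz resolution), and band
power is the mean spectral density inside each of the six canonical bands:
delta 1-4, theta 4-7, alpha 7-13, beta 13-30, low-gamma 30-48 and
high-gamma 52-80 Hz.  The 48-52 Hz mains gap falls between the gamma bands
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .timeseries import ParcelTimeSeries

__all__ = [
    "BandScheme",
    "CANONICAL_BANDS",
    "PowerSpectrum",
    "BandPower",
    "ConditioningParams",
    "ConditioningResult",
    "condition",
    "zscore",
    "welch_psd",
    "band_power",
]

CANONICAL_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 7.0),
    ("alpha", 7.0, 13.0),
    ("beta", 13.0, 30.0),
    ("low_gamma", 30.0, 48.0),
    ("high_gamma", 52.0, 80.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands (name, f_lo, f_hi) in Hz."""

    bands: tuple[tuple[str, float, float], ...] = CANONICAL_BANDS

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name!r}: f_lo must be < f_hi")
        ordered = sorted(self.bands, key=lambda b: b[1])
        for (n1, _, hi1), (n2, lo2, _) in zip(ordered, ordered[1:]):
            if lo2 < hi1:
                raise ValueError(f"bands {n1!r} and {n2!r} overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class PowerSpectrum:
    """One subject's parcels-by-frequencies Welch PSD (one-sided density)."""

    freqs: np.ndarray
    psd: np.ndarray
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.psd.ndim != 2 or self.psd.shape[1] != len(self.freqs):
            raise ValueError("psd must be parcels x freqs")
        if (self.psd < 0).any():
            raise ValueError("PSD values must be non-negative")


@dataclass(frozen=True)
class BandPower:
    """Parcels-by-bands matrix of mean in-band spectral density."""

    values: np.ndarray
    scheme: BandScheme

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.scheme):
            raise ValueError("values must be parcels x bands")
        if (self.values < 0).any():
            raise ValueError("band power must be non-negative")


@dataclass(frozen=True)
class ConditioningParams:
    notch_freqs: tuple[float, ...] = (50.0, 100.0)
    notch_q: float = 30.0
    target_fs: float = 250.0
    bandpass: tuple[float, float] = (1.0, 80.0)
    bandpass_order: int = 5
    bad_window_s: float = 1.0
    bad_mad_k: float = 5.0
    max_bad_fraction: float = 0.5


@dataclass(frozen=True)
class ConditioningResult:
    """Conditioned time series plus the excised bad-segment log.

    ``excised_segments`` holds (start, stop) sample indices at the resampled
    rate, before excision, merged over adjacent flagged windows.
    """

    timeseries: ParcelTimeSeries
    excised_segments: tuple[tuple[int, int], ...]


def _flag_bad_windows(data: np.ndarray, fs: float, window_s: float, k: float) -> np.ndarray:
    """Robust outlier rule: flag 1-s windows whose log-variance (averaged
    over parcels) exceeds median + k * MAD across windows."""
    win = int(round(window_s * fs))
    n_win = data.shape[1] // win
    if n_win < 3:
        return np.zeros(max(n_win, 0), dtype=bool)
    segs = data[:, : n_win * win].reshape(data.shape[0], n_win, win)
    logvar = np.log(segs.var(axis=2).mean(axis=0) + 1e-300)
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med))
    if mad == 0:
        return np.zeros(n_win, dtype=bool)
    return logvar > med + k * mad


def condition(
    ts: ParcelTimeSeries, params: ConditioningParams = ConditioningParams()
) -> ConditioningResult:
    """Notch, resample to 250 Hz, excise bad segments, band-pass 1-80 Hz.

    Raises if more than ``max_bad_fraction`` of the recording is flagged
    bad (an unusable recording).
    """
    if ts.fs < params.target_fs:
        raise ValueError(f"input sampling rate {ts.fs} Hz below target {params.target_fs} Hz")
    data = ts.data
    nyq_in = ts.fs / 2
    for f0 in params.notch_freqs:
        if f0 >= nyq_in:
            continue
        b, a = signal.iirnotch(f0, params.notch_q, fs=ts.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    if ts.fs != params.target_fs:
        ratio = Fraction(params.target_fs / ts.fs).limit_denominator(1000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
    fs = params.target_fs

    flags = _flag_bad_windows(data, fs, params.bad_window_s, params.bad_mad_k)
    win = int(round(params.bad_window_s * fs))
    segments: list[tuple[int, int]] = []
    if flags.any():
        if flags.mean() > params.max_bad_fraction:
            raise ValueError(
                f"{flags.mean():.0%} of windows flagged bad: unusable recording"
            )
        idx = np.flatnonzero(flags)
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                segments.append((start * win, (prev + 1) * win))
                start = i
            prev = i
        segments.append((start * win, (prev + 1) * win))
        keep = np.ones(data.shape[1], dtype=bool)
        for a0, b0 in segments:
            keep[a0:b0] = False
        data = data[:, keep]

    lo, hi = params.bandpass
    sos = signal.butter(params.bandpass_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    return ConditioningResult(ts.with_data(data, fs=fs), tuple(segments))


def zscore(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Standardize each parcel time course to mean 0, variance 1."""
    mu = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, keepdims=True)
    if (sd == 0).any():
        const = [ts.parcel_order[i] for i in np.flatnonzero(sd[:, 0] == 0)]
        raise ValueError(f"constant parcel time course(s): {const}")
    return ts.with_data((ts.data - mu) / sd)


def welch_psd(
    ts: ParcelTimeSeries,
    window_s: float = 2.0,
    window: str = "hann",
    overlap_frac: float = 0.5,
) -> PowerSpectrum:
    """Welch PSD with a Hann window (default 2 s, 50% overlap, one-sided)."""
    nperseg = int(round(window_s * ts.fs))
    if nperseg > ts.n_samples:
        raise ValueError(
            f"window of {window_s} s ({nperseg} samples) longer than data ({ts.n_samples})"
        )
    freqs, psd = signal.welch(
        ts.data,
        fs=ts.fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        axis=1,
        detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(freqs=freqs, psd=psd, window_s=window_s, fs=ts.fs)


def band_power(psd: PowerSpectrum, scheme: BandScheme = BandScheme()) -> BandPower:
    """Mean PSD per band over bins with f_lo <= f < f_hi (half-open)."""
    values = np.empty((psd.psd.shape[0], len(scheme)))
    for j, (name, lo, hi) in enumerate(scheme.bands):
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        if not mask.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}) contains no frequency bins")
        values[:, j] = psd.psd[:, mask].mean(axis=1)
    return BandPower(values=values, scheme=scheme)
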