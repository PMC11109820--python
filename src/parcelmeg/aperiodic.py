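"""Spectral parameterization: split a PSD into aperiodic and periodic parts.

The model in log10 power is

    log10 PSD(f) = b - chi * log10(f) + sum_k h_k * exp(-(f - c_k)^2 / (2 s_k^2))

with offset ``b``, aperiodic exponent ``chi`` (chi > 0 for downward-sloping
spectra; a *lower* exponent means a *flatter* spectrum), and Gaussian peaks
in linear frequency with heights in log10 power.  The exponent is the
complexity metric carried into group statistics.

Fitting is iterative: a robust straight-line fit to log10 PSD vs log10 f,
peak extraction from the flattened spectrum until the largest residual falls
below threshold, a joint refit of all peaks, and a final aperiodic refit on
the peak-removed spectrum.  Defaults follow common practice for fixed-mode
parameterization of 1-70 Hz resting spectra: peak width 0.5-12 Hz, minimum
peak height 0.05 log10 units, relative peak threshold 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["AperiodicSettings", "AperiodicFit", "fit_aperiodic", "fit_spectrum_matrix"]


@dataclass(frozen=True)
class AperiodicSettings:
    """Tunables of the spectral parameterization.

    ``peak_width_limits`` bound the reported peak width (2 * Gaussian SD) in
    Hz.  ``peak_threshold`` is relative: a candidate peak must exceed
    ``peak_threshold`` times the SD of the flattened spectrum, and always
    ``min_peak_height`` (log10-power units).  ``max_n_peaks`` caps the
    extraction loop; the reference semantics of "unlimited" peaks are kept
    by a generous default with a warning when the cap is hit.
    """

    fit_range: tuple[float, float] = (1.0, 70.0)
    peak_width_limits: tuple[float, float] = (0.5, 12.0)
    max_n_peaks: int = 20
    min_peak_height: float = 0.05
    peak_threshold: float = 2.0
    robust_percentile: float = 97.5
    robust_passes: int = 2


@dataclass(frozen=True)
class AperiodicFit:
    """Fitted aperiodic parameters plus detected peaks.

    ``peaks`` holds (center Hz, height in log10 power, width Hz) tuples,
    width being twice the Gaussian SD.
    """

    offset: float
    exponent: float
    fit_range: tuple[float, float]
    r_squared: float
    peaks: tuple[tuple[float, float, float], ...]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _linear_fit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return intercept, -slope  # offset, exponent


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray, settings: AperiodicSettings) -> tuple[float, float]:
    """OLS line fit, then drop bins in the highest tail of positive residuals
    (oscillatory peaks push log power up, never down) and refit."""
    b, chi = _linear_fit(logf, logp)
    for _ in range(settings.robust_passes):
        resid = logp - (b - chi * logf)
        thresh = np.percentile(resid, settings.robust_percentile)
        keep = resid <= max(thresh, 0.0)
        if keep.sum() < 3:
            break
        b, chi = _linear_fit(logf[keep], logp[keep])
    return b, chi


def _gaussian(f: np.ndarray, center: float, height: float, std: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * std**2))


def _multi_gaussian(f: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        out += _gaussian(f, params[i], params[i + 1], params[i + 2])
    return out


def _gaussian_jac(f: np.ndarray, center: float, height: float, std: float) -> np.ndarray:
    g = np.exp(-((f - center) ** 2) / (2.0 * std**2))
    dc = height * g * (f - center) / std**2
    dh = g
    ds = height * g * (f - center) ** 2 / std**3
    return np.column_stack([dc, dh, ds])


def _multi_gaussian_jac(f: np.ndarray, *params: float) -> np.ndarray:
    return np.hstack(
        [_gaussian_jac(f, params[i], params[i + 1], params[i + 2])
         for i in range(0, len(params), 3)]
    )


def _extract_peaks(
    freqs: np.ndarray, flat: np.ndarray, settings: AperiodicSettings, label: str
) -> list[tuple[float, float, float]]:
    lo_std = settings.peak_width_limits[0] / 2.0
    hi_std = settings.peak_width_limits[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    resid = flat.copy()
    for _ in range(settings.max_n_peaks):
        i_max = int(np.argmax(resid))
        height = resid[i_max]
        if height < max(settings.peak_threshold * resid.std(), settings.min_peak_height):
            break
        center = freqs[i_max]
        # half-height extent -> Gaussian SD guess (FWHM = 2.355 sigma)
        half = height / 2.0
        i_left = i_max
        while i_left > 0 and resid[i_left] > half:
            i_left -= 1
        i_right = i_max
        while i_right < len(resid) - 1 and resid[i_right] > half:
            i_right += 1
        fwhm = max(freqs[i_right] - freqs[i_left], freqs[1] - freqs[0])
        std = float(np.clip(fwhm / 2.355, lo_std, hi_std))
        # fast unbounded fit; the result is only a guess for the joint
        # bounded refit, so parameters are clipped into range afterwards.
        # The unbounded solver can diverge on flat residual shapes; fall
        # back to the bounded solver in that case.
        popt = None
        try:
            with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
                # a diverged LM fit cannot estimate a covariance; the
                # covariance is unused and divergence triggers the bounded
                # fallback below
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _gaussian,
                    freqs,
                    resid,
                    p0=[center, height, std],
                    jac=_gaussian_jac,
                    method="lm",
                    maxfev=2000,
                )
            if not np.all(np.isfinite(popt)):
                popt = None
        except RuntimeError:
            popt = None
        if popt is None:
            try:
                popt, _ = curve_fit(
                    _gaussian,
                    freqs,
                    resid,
                    p0=[center, height, std],
                    bounds=([freqs[0], 0.0, lo_std], [freqs[-1], np.inf, hi_std]),
                    jac=_gaussian_jac,
                    maxfev=2000,
                )
            except RuntimeError as exc:
                raise RuntimeError(f"peak fit failed for parcel {label!r}") from exc
        popt = [
            float(np.clip(popt[0], freqs[0], freqs[-1])),
            float(max(popt[1], 0.0)),
            float(np.clip(abs(popt[2]), lo_std, hi_std)),
        ]
        resid = resid - _gaussian(freqs, *popt)
        guesses.append((popt[0], popt[1], popt[2]))
    else:
        warnings.warn(
            f"peak extraction hit the {settings.max_n_peaks}-peak cap for parcel {label!r}",
            RuntimeWarning,
            stacklevel=3,
        )
    return guesses


def fit_aperiodic(
    psd_row: np.ndarray,
    freqs: np.ndarray,
    settings: AperiodicSettings = AperiodicSettings(),
    label: str = "?",
) -> AperiodicFit:
    """Parameterize one parcel's PSD within ``settings.fit_range``.

    Raises on non-positive PSD values inside the range or on a
    non-convergent joint peak fit (the error names the parcel).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd_row = np.asarray(psd_row, dtype=float)
    lo, hi = settings.fit_range
    mask = (freqs >= lo) & (freqs <= hi)
    f = freqs[mask]
    p = psd_row[mask]
    if f.size < 5:
        raise ValueError("too few frequency bins inside the fit range")
    if (p <= 0).any():
        raise ValueError(f"non-positive PSD values in fit range for parcel {label!r}")
    logf = np.log10(f)
    logp = np.log10(p)

    b, chi = _robust_aperiodic(logf, logp, settings)
    flat = logp - (b - chi * logf)
    peaks = _extract_peaks(f, flat, settings, label)

    if peaks:
        p0 = np.array(peaks).ravel()
        lo_std = settings.peak_width_limits[0] / 2.0
        hi_std = settings.peak_width_limits[1] / 2.0
        lower = np.tile([f[0], 0.0, lo_std], len(peaks))
        upper = np.tile([f[-1], np.inf, hi_std], len(peaks))
        try:
            popt, _ = curve_fit(
                _multi_gaussian, f, flat, p0=p0, bounds=(lower, upper),
                jac=_multi_gaussian_jac, maxfev=5000,
                xtol=1e-5, ftol=1e-5, gtol=1e-5,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"joint peak refit failed for parcel {label!r}") from exc
        peak_model = _multi_gaussian(f, *popt)
        peaks = [
            (float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
            for i in range(0, len(popt), 3)
        ]
    else:
        peak_model = np.zeros_like(f)

    b, chi = _robust_aperiodic(logf, logp - peak_model, settings)
    model = b - chi * logf + peak_model
    ss_res = float(((logp - model) ** 2).sum())
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=float(b),
        exponent=float(chi),
        fit_range=(lo, hi),
        r_squared=max(0.0, min(1.0, r2)),
        peaks=tuple((c, h, 2.0 * s) for c, h, s in peaks),
    )


def fit_spectrum_matrix(
    psd: np.ndarray,
    freqs: np.ndarray,
    settings: AperiodicSettings = AperiodicSettings(),
    labels: tuple[str, ...] | None = None,
) -> list[AperiodicFit]:
    """Fit every row of a parcels-by-frequencies PSD matrix."""
    labels = labels or tuple(str(i) for i in range(psd.shape[0]))
    return [fit_aperiodic(psd[i], freqs, settings, label=labels[i]) for i in range(psd.shape[0])]
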