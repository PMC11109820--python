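"""Synthetic resting-state cohorts with known planted effects.

Every downstream stage of the pipeline is exercised against cohorts whose
ground truth is known exactly.  Each parcel time course is a sum over the
six canonical bands of a band-limited oscillation with a slowly varying
amplitude envelope, riding on an aperiodic 1/f^chi background:

    x_p(t) = sum_b A_pb * m_pb(t) * c_pb(t) + s * a_p(t)

* carriers ``c`` are white noise band-passed with a 4th-order Butterworth at
  the canonical band edges, then normalized to constant modulus (divided by
  their instantaneous Hilbert amplitude) so the signal's envelope is the
  modulator itself and planted envelope correlations up to 0.9 are
  reachable;
* modulators ``m`` are rectified low-pass (<1 Hz) Gaussian noises; envelope
  coupling between parcels is induced by mixing a shared modulator into each
  member of a coupling group, with the mixing weight calibrated numerically
  (bisection against the connectivity module) to hit the target envelope
  correlation;
* the aperiodic background ``a`` is synthesized in the frequency domain
  (amplitude proportional to f^(-chi/2), random phases) so its spectrum is
  an exact power law.

Planted group/severity effects scale band amplitudes (multiplicative
factor per unit of a driving covariate), shift the aperiodic exponent
(additive), or raise envelope-coupling targets, within named ROI groups.
An all-zero effect specification yields exchangeable groups (a null
cohort).  Covariate marginals default to the study cohort they emulate:
36 ALS / 51 controls from 92 recruited (4 excluded for missing scans, 1
for an unusable recording), age ~ N(61, 11) truncated to 35-85, 65% male,
91% right-handed, ALSFRS-R ~ round(N(37.6, 7)) clipped to 10-48, UMN ~
round(N(9, 4.4)) clipped at 0, and years from onset log-normal matched to
mean 2.1, SD 1.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import COHORT_COLUMNS, CohortTable
from .connectivity import aec, band_envelope
from .parcellation import Parcellation, make_parcellation
from .spectral import CANONICAL_BANDS
from .timeseries import ParcelTimeSeries

__all__ = [
    "NoiseParams",
    "BandPowerEffect",
    "ExponentEffect",
    "ConnectivityEffect",
    "EffectSpec",
    "CohortConfig",
    "generate_subject",
    "generate_cohort",
    "calibrate_coupling_weight",
    "study_effects",
]

_BAND_EDGES = {name: (lo, hi) for name, lo, hi in CANONICAL_BANDS}

# resting MEG-like band amplitudes relative to a unit-SD 1/f background:
# pronounced alpha peak, clear beta hump, modest gamma elevation, and
# delta/theta riding mostly on the aperiodic slope
_DEFAULT_AMPLITUDES = {
    "delta": 0.35,
    "theta": 0.3,
    "alpha": 0.8,
    "beta": 0.6,
    "low_gamma": 0.18,
    "high_gamma": 0.15,
}

_COVARIATES = ("group", "alsfrs_change", "umn")


@dataclass(frozen=True)
class NoiseParams:
    """Subject-level signal model parameters.

    ``chi`` is the aperiodic exponent of the 1/f background,
    ``aperiodic_scale`` its standard deviation relative to the unit-variance
    band amplitudes.  ``amp_jitter_sd`` / ``chi_jitter_sd`` are
    between-subject log-normal / normal jitters that give cohort statistics
    realistic subject-to-subject spread.  ``coupling`` lists baseline
    envelope-coupling groups as (parcel labels, band, target AEC).
    """

    chi: float = 1.5
    aperiodic_scale: float = 1.0
    band_amplitudes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    amp_jitter_sd: float = 0.1
    chi_jitter_sd: float = 0.1
    modulator_cutoff_hz: float = 0.5
    coupling: tuple[tuple[tuple[str, ...], str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.chi <= 0:
            raise ValueError("aperiodic exponent chi must be > 0")
        for band, amp in self.band_amplitudes.items():
            if band not in _BAND_EDGES:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError(f"amplitude for {band!r} must be >= 0")


@dataclass(frozen=True)
class BandPowerEffect:
    """Multiply band power in an ROI by ``factor`` per unit of covariate."""

    roi: str
    band: str
    factor: float
    covariate: str = "group"

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("band power factor must be > 0")
        if self.covariate not in _COVARIATES:
            raise ValueError(f"unknown driving covariate {self.covariate!r}")


@dataclass(frozen=True)
class ExponentEffect:
    """Shift the aperiodic exponent in an ROI by ``shift`` per unit covariate."""

    roi: str
    shift: float
    covariate: str = "group"

    def __post_init__(self) -> None:
        if self.covariate not in _COVARIATES:
            raise ValueError(f"unknown driving covariate {self.covariate!r}")


@dataclass(frozen=True)
class ConnectivityEffect:
    """Raise envelope-coupling targets among ROI parcels.

    The target AEC for every pair inside the ROI is
    ``base + increment * covariate``; targets above 0.9 are unreachable and
    rejected at generation time.
    """

    roi: str
    band: str
    base: float = 0.1
    increment: float = 0.0
    covariate: str = "alsfrs_change"

    def __post_init__(self) -> None:
        if not 0 <= self.base <= 0.9:
            raise ValueError("base envelope correlation must lie in [0, 0.9]")
        if self.covariate not in _COVARIATES:
            raise ValueError(f"unknown driving covariate {self.covariate!r}")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects; the empty spec is the null cohort."""

    band_power: tuple[BandPowerEffect, ...] = ()
    exponent: tuple[ExponentEffect, ...] = ()
    connectivity: tuple[ConnectivityEffect, ...] = ()

    @property
    def is_null(self) -> bool:
        return not (self.band_power or self.exponent or self.connectivity)


def study_effects() -> EffectSpec:
    """The default planted effect structure emulating the disease signature:
    sensorimotor beta power loss and frontal high-gamma gain with group,
    frontal exponent flattening with group, and temporal theta envelope
    hyperconnectivity scaling with the change-from-baseline score."""
    return EffectSpec(
        band_power=(
            BandPowerEffect("sensorimotor", "beta", 0.7, "group"),
            BandPowerEffect("frontal", "high_gamma", 1.3, "group"),
        ),
        exponent=(ExponentEffect("frontal", -0.3, "group"),),
        connectivity=(ConnectivityEffect("temporal", "theta", base=0.05, increment=0.005),),
    )


def _covariate_value(covariates, name: str) -> float:
    group = covariates["group"]
    if name == "group":
        return 1.0 if group == "ALS" else 0.0
    if group != "ALS":
        return 0.0
    if name == "alsfrs_change":
        return 48.0 - float(covariates["alsfrs_r"])
    if name == "umn":
        return float(covariates["umn_score"])
    raise ValueError(f"unknown covariate {name!r}")


def _lowpass_noise(rng: np.random.Generator, shape, fs: float, cutoff: float) -> np.ndarray:
    """Unit-SD low-pass Gaussian noise; last axis is time, rows independent."""
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = z.std(axis=-1, keepdims=True)
    return z / np.where(sd > 0, sd, 1.0)


def _constant_modulus_carrier(
    rng: np.random.Generator, shape, band: tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    narrow = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    analytic = signal.hilbert(narrow, axis=-1)
    mag = np.abs(analytic)
    mag[mag == 0] = 1.0
    return np.real(analytic / mag)


def _band_signal(
    z: np.ndarray,
    rng: np.random.Generator,
    band: tuple[float, float],
    fs: float,
    trim: int = 0,
    order: int = 4,
) -> np.ndarray:
    """Unit-SD band-limited process with envelope |z|.

    The modulated carrier is band-passed a second time: constant-modulus
    normalization and amplitude modulation both regrow spectral sidebands
    outside the band, and the re-filter confines each process to its own
    band so cross-band leakage stays negligible.  ``trim`` samples are cut
    from each end *after* filtering (zero-phase filtering of finite records
    leaves edge transients; the caller generates a burn-in margin), and the
    unit-SD normalization applies to the retained interior.
    """
    x = np.abs(z) * _constant_modulus_carrier(rng, z.shape, band, fs, order=order)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    if trim:
        x = x[..., trim:-trim]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


# burn-in margin (seconds) discarded from each end of every filtered
# realization; several time constants of the slowest (0.5 Hz) filter
_BURN_IN_S = 3.0


def _aperiodic_background(
    rng: np.random.Generator, n: int, fs: float, chi, f_min: float = 1.0
) -> np.ndarray:
    """Exact-spectrum 1/f^chi noise via frequency-domain synthesis, unit SD.

    ``chi`` may be a vector; one row is synthesized per exponent.  Content
    below ``f_min`` is omitted (preprocessing high-passes it anyway), so the
    unit SD refers to the analysis range rather than being swallowed by the
    divergent ultra-slow part of the power law.
    """
    chi_arr = np.atleast_1d(np.asarray(chi, dtype=float))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros((chi_arr.size, freqs.size))
    keep = freqs >= f_min
    amp[:, keep] = freqs[keep] ** (-chi_arr[:, None] / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(chi_arr.size, freqs.size))
    x = np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)
    x = x / x.std(axis=-1, keepdims=True)
    return x[0] if np.isscalar(chi) or np.ndim(chi) == 0 else x


_coupling_cache: dict[tuple, float] = {}


def _pair_aec(w: float, band_name: str, noise: "NoiseParams", fs: float, n: int,
              rng_seed: int) -> float:
    """Measured envelope correlation of a two-parcel coupling at weight w.

    The calibration pair is a faithful miniature subject: all configured
    bands plus the aperiodic background are present, so in-band dilution by
    neighboring bands and by the 1/f background is accounted for.  The
    measurement runs through the connectivity module itself.
    """
    rng = np.random.default_rng(rng_seed)
    cutoff = noise.modulator_cutoff_hz
    trim = int(_BURN_IN_S * fs)
    n_tot = n + 2 * trim
    data = np.zeros((2, n))
    for b, base in noise.band_amplitudes.items():
        if base == 0:
            continue
        z = _lowpass_noise(rng, (2, n_tot), fs, cutoff)
        if b == band_name:
            zs = _lowpass_noise(rng, n_tot, fs, cutoff)
            z = np.sqrt(1 - w**2) * z + w * zs
        data += base * _band_signal(z, rng, _BAND_EDGES[b], fs, trim=trim)
    if noise.aperiodic_scale > 0:
        data += noise.aperiodic_scale * _aperiodic_background(
            rng, n, fs, np.array([noise.chi, noise.chi])
        )
    env = band_envelope(data, _BAND_EDGES[band_name], fs)
    return float(aec(env, edge_trim_s=1.0, fs=fs).aec[0, 1])


def calibrate_coupling_weight(
    band_name: str,
    target: float,
    noise: "NoiseParams",
    fs: float = 250.0,
    duration_s: float = 240.0,
    tol: float = 0.01,
    n_calibration_runs: int = 3,
) -> float:
    """Mixing weight whose measured pair AEC hits ``target``, by bisection.

    The calibration run uses a fixed internal seed so the mapping is a pure
    function of its arguments (cached per signal-model configuration).
    """
    if not 0 <= target <= 0.9:
        raise ValueError(f"target envelope correlation {target} outside reachable [0, 0.9]")
    key = (
        band_name,
        round(target, 4),
        fs,
        duration_s,
        noise.chi,
        noise.aperiodic_scale,
        noise.modulator_cutoff_hz,
        tuple(sorted(noise.band_amplitudes.items())),
    )
    if key in _coupling_cache:
        return _coupling_cache[key]
    if target == 0:
        _coupling_cache[key] = 0.0
        return 0.0
    n = int(duration_s * fs)

    def measure(w: float) -> float:
        runs = [
            _pair_aec(w, band_name, noise, fs, n, rng_seed=987654321 + k)
            for k in range(n_calibration_runs)
        ]
        return float(np.mean(runs))

    r_max = measure(1.0)
    if target > r_max + tol:
        raise ValueError(
            f"target envelope correlation {target} unreachable in band {band_name!r}: "
            f"maximum attainable under this signal model is {r_max:.3f}"
        )
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        r = measure(mid)
        if abs(r - target) < tol:
            lo = hi = mid
            break
        if r < target:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    _coupling_cache[key] = w
    return w


def _resolve_couplings(
    parc: Parcellation,
    noise: NoiseParams,
    effects: EffectSpec,
    covariates,
) -> dict[str, list[tuple[tuple[int, ...], float]]]:
    """Per band: list of (member indices, target AEC) coupling groups."""
    groups: dict[str, list[tuple[tuple[int, ...], float]]] = {}
    for members, band, target in noise.coupling:
        idx = tuple(parc.index(m) for m in members)
        groups.setdefault(band, []).append((idx, float(target)))
    for eff in effects.connectivity:
        cov = _covariate_value(covariates, eff.covariate)
        target = eff.base + eff.increment * cov
        if target > 0.9:
            raise ValueError(
                f"connectivity target {target:.3f} in {eff.roi}/{eff.band} exceeds reachable 0.9"
            )
        idx = tuple(parc.roi_indices(eff.roi))
        groups.setdefault(eff.band, []).append((idx, float(max(target, 0.0))))
    for band, glist in groups.items():
        seen: set[int] = set()
        for idx, _ in glist:
            if seen & set(idx):
                raise ValueError(
                    f"overlapping coupling groups in band {band!r}: a parcel cannot "
                    "belong to two groups in the same band"
                )
            seen |= set(idx)
    return groups


def generate_subject(
    parcellation: Parcellation,
    covariates,
    effect_spec: EffectSpec,
    noise_params: NoiseParams,
    seed: int,
    duration_s: float = 540.0,
    fs: float = 250.0,
) -> ParcelTimeSeries:
    """Simulate one subject's parcel time courses.

    Deterministic under ``seed``.  Raises if ``fs`` cannot represent the
    highest requested band or if a coupling target is unreachable.
    """
    top_edge = max(hi for _, hi in (_BAND_EDGES[b] for b in noise_params.band_amplitudes))
    if fs < 2 * top_edge:
        raise ValueError(f"fs = {fs} Hz below twice the top band edge ({top_edge} Hz)")
    rng = np.random.default_rng(seed)
    P = parcellation.n_parcels
    n = int(round(duration_s * fs))

    # per-parcel, per-band amplitudes with planted multiplicative effects
    bands = list(noise_params.band_amplitudes)
    amp = np.empty((P, len(bands)))
    for j, b in enumerate(bands):
        base = noise_params.band_amplitudes[b]
        amp[:, j] = base * np.exp(rng.normal(0, noise_params.amp_jitter_sd, size=P))
    for eff in effect_spec.band_power:
        cov = _covariate_value(covariates, eff.covariate)
        j = bands.index(eff.band)
        # power scales with factor^cov, amplitude with its square root
        amp[parcellation.roi_indices(eff.roi), j] *= eff.factor ** (cov / 2.0)

    chi = np.full(P, noise_params.chi) + rng.normal(0, noise_params.chi_jitter_sd, size=P)
    for eff in effect_spec.exponent:
        cov = _covariate_value(covariates, eff.covariate)
        chi[parcellation.roi_indices(eff.roi)] += eff.shift * cov
    chi = np.clip(chi, 0.1, None)

    couplings = _resolve_couplings(parcellation, noise_params, effect_spec, covariates)

    data = np.zeros((P, n))
    cutoff = noise_params.modulator_cutoff_hz
    trim = int(_BURN_IN_S * fs)
    n_tot = n + 2 * trim
    for j, b in enumerate(bands):
        edges = _BAND_EDGES[b]
        z = _lowpass_noise(rng, (P, n_tot), fs, cutoff)
        for idx, target in couplings.get(b, []):
            w = calibrate_coupling_weight(b, target, noise_params, fs=fs)
            shared = _lowpass_noise(rng, n_tot, fs, cutoff)
            z[list(idx)] = np.sqrt(1 - w**2) * z[list(idx)] + w * shared
        data += amp[:, j : j + 1] * _band_signal(z, rng, edges, fs, trim=trim)
    if noise_params.aperiodic_scale > 0:
        data += noise_params.aperiodic_scale * _aperiodic_background(rng, n, fs, chi)

    return ParcelTimeSeries(
        subject_id=str(covariates.get("subject_id", "sim")),
        data=data,
        fs=fs,
        parcel_order=parcellation.labels,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings; defaults emulate the study cohort."""

    n_als: int = 36
    n_control: int = 51
    n_recruited: int = 92
    n_excluded_missing_scan: int = 4
    n_excluded_noisy: int = 1
    n_pairs: int = 26
    duration_range_s: tuple[float, float] = (480.0, 600.0)
    fs: float = 250.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    effects: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        if self.n_als <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        analysed = self.n_recruited - self.n_excluded_missing_scan - self.n_excluded_noisy
        if analysed != self.n_als + self.n_control:
            raise ValueError(
                f"cohort accounting mismatch: {self.n_recruited} recruited - "
                f"{self.n_excluded_missing_scan} - {self.n_excluded_noisy} excluded "
                f"= {analysed}, but group sizes sum to {self.n_als + self.n_control}"
            )
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("invalid duration range")


def _draw_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_als + config.n_control
    rows = []
    # log-normal parameters matched to mean 2.1 y, SD 1.3 y
    sigma2 = np.log(1 + (1.3 / 2.1) ** 2)
    mu = np.log(2.1) - sigma2 / 2
    for i in range(n):
        group = "ALS" if i < config.n_als else "control"
        age = float(np.clip(rng.normal(61, 11), 35, 85))
        sex = "M" if rng.random() < 0.65 else "F"
        hand = "right" if rng.random() < 0.91 else "left"
        if group == "ALS":
            alsfrs = float(np.clip(np.round(rng.normal(37.6, 7.0)), 10, 48))
            umn = float(max(np.round(rng.normal(9.0, 4.4)), 0))
            onset = float(rng.lognormal(mu, np.sqrt(sigma2)))
        else:
            alsfrs, umn, onset = np.nan, np.nan, np.nan
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "group": group,
                "age": age,
                "sex": sex,
                "handedness": hand,
                "alsfrs_r": alsfrs,
                "umn_score": umn,
                "years_from_onset": onset,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _affected_cells(parc: Parcellation, effects: EffectSpec) -> dict:
    power = sorted(
        {(label, eff.band) for eff in effects.band_power for label in parc.roi_groups[eff.roi]}
    )
    exponent = sorted({label for eff in effects.exponent for label in parc.roi_groups[eff.roi]})
    # Side effects that are real consequences of the planted effects, not
    # false positives: an exponent shift redistributes the 1/f background
    # across *all* bands of those parcels, and a band-power change alters a
    # parcel's total variance, so the *relative* (z-scored) power of its
    # other bands shifts oppositely.
    power_parcels = {label for eff in effects.band_power for label in parc.roi_groups[eff.roi]}
    power_secondary = sorted(
        ({(label, band) for label in exponent for band in _BAND_EDGES}
         | {(label, band) for label in power_parcels for band in _BAND_EDGES})
        - set(power)
    )
    connectivity = sorted(
        {(eff.roi, eff.band, eff.base, eff.increment, eff.covariate) for eff in effects.connectivity}
    )
    return {
        "power": [list(c) for c in power],
        "power_secondary": [list(c) for c in power_secondary],
        "exponent": list(exponent),
        "connectivity": [list(c) for c in connectivity],
    }


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[CohortTable, list[ParcelTimeSeries], dict]:
    """Simulate a full cohort: covariates, time courses and ground truth.

    Per-subject seeds are spawned from the master seed with
    ``numpy.random.SeedSequence(seed).spawn`` in subject order, so the run
    is reproducible subject-by-subject.
    """
    master = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(master.spawn(1)[0])
    df = _draw_covariates(config, cov_rng)
    cohort = CohortTable(df)
    parc = make_parcellation(config.n_pairs)

    lo, hi = config.duration_range_s
    subject_seeds = master.spawn(len(df) + 1)[1:]
    series = []
    for (_, row), ss in zip(df.iterrows(), subject_seeds):
        sub_rng = np.random.default_rng(ss)
        duration = float(sub_rng.uniform(lo, hi))
        ts = generate_subject(
            parc,
            row,
            config.effects,
            config.noise,
            seed=int(sub_rng.integers(0, 2**31 - 1)),
            duration_s=duration,
            fs=config.fs,
        )
        series.append(ts)

    ground_truth = {
        "seed": int(seed),
        "n_als": config.n_als,
        "n_control": config.n_control,
        "n_recruited": config.n_recruited,
        "n_excluded": config.n_excluded_missing_scan + config.n_excluded_noisy,
        "null": config.effects.is_null,
        "affected": _affected_cells(parc, config.effects),
    }
    return cohort, series, ground_truth
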