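"""End-to-end pipeline driver.

Stage order mirrors the analysis it implements: simulate (or load) parcel
time courses, condition, z-score, leakage-correct, compute Welch spectra /
band power / aperiodic exponents / band-wise envelope connectivity, run the
permutation GLM for each requested mode and metric, and finally the nested
LOOCV severity prediction on the patient group.  A manifest records the
seeds, configuration and per-stage warnings so every random draw in a run
is attributable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .aperiodic import fit_spectrum_matrix
from .config import RunConfig, save_config
from .connectivity import aec, band_envelope, summarize, symmetric_orthogonalize
from .glm import build_design, permutation_maxt
from .parcellation import Parcellation, make_parcellation
from .predict import build_features, nested_loocv
from .simulate import generate_cohort
from .spectral import BandScheme, band_power, condition, welch_psd, zscore
from .timeseries import ParcelTimeSeries

__all__ = ["extract_features", "run_pipeline"]


def extract_features(
    series: list[ParcelTimeSeries],
    parc: Parcellation,
    config: RunConfig,
    scheme: BandScheme = BandScheme(),
) -> dict:
    """Per-subject spectral and connectivity metrics for a set of recordings.

    Returns dict with keys ``power`` (subject -> parcels x bands),
    ``exponent`` (subject -> parcels), ``aperiodic_fits``, ``aec`` (subject
    -> bands x parcels x parcels) and ``summaries`` (tidy DataFrame).
    """
    power: dict[str, np.ndarray] = {}
    exponent: dict[str, np.ndarray] = {}
    fits: dict[str, list] = {}
    aec_mats: dict[str, np.ndarray] = {}
    summary_rows = []
    for ts in series:
        if config.apply_conditioning:
            ts = condition(ts, config.conditioning).timeseries
        ts = zscore(ts)
        psd = welch_psd(ts, window_s=config.welch_window_s, overlap_frac=config.welch_overlap)
        power[ts.subject_id] = band_power(psd, scheme).values
        parcel_fits = fit_spectrum_matrix(
            psd.psd, psd.freqs, config.aperiodic, labels=ts.parcel_order
        )
        fits[ts.subject_id] = parcel_fits
        exponent[ts.subject_id] = np.array([f.exponent for f in parcel_fits])

        ortho = symmetric_orthogonalize(ts.data)
        mats = np.empty((len(scheme), parc.n_parcels, parc.n_parcels))
        for b, (name, lo, hi) in enumerate(scheme.bands):
            env = band_envelope(ortho, (lo, hi), ts.fs)
            conn = aec(env, band=name, edge_trim_s=config.edge_trim_s, fs=ts.fs)
            mats[b] = conn.aec
            summ = summarize(conn, parc)
            for i, label in enumerate(parc.labels):
                summary_rows.append(
                    {
                        "subject": ts.subject_id,
                        "parcel": label,
                        "band": name,
                        "global": summ.global_mean[i],
                        "intra": summ.intra_mean[i],
                        "inter": summ.inter_mean[i],
                    }
                )
        aec_mats[ts.subject_id] = mats
    return {
        "power": power,
        "exponent": exponent,
        "aperiodic_fits": fits,
        "aec": aec_mats,
        "summaries": pd.DataFrame(summary_rows),
    }


def _metric_array(metric: str, features: dict, subjects: list[str], scheme: BandScheme):
    """Stack a per-subject metric into subjects x parcels x bands."""
    if metric == "power":
        return np.stack([features["power"][s] for s in subjects])
    if metric == "exponent":
        return np.stack([features["exponent"][s][:, None] for s in subjects])
    if metric.startswith("aec-"):
        kind = metric.split("-", 1)[1]
        summ = features["summaries"]
        wide = summ.pivot_table(
            index="subject", columns=["parcel", "band"], values=kind, sort=False
        )
        parcels = summ["parcel"].unique()
        bands = list(scheme.names)
        arr = np.empty((len(subjects), len(parcels), len(bands)))
        for i, s in enumerate(subjects):
            for j, p in enumerate(parcels):
                for k, b in enumerate(bands):
                    arr[i, j, k] = wide.loc[s, (p, b)]
        return arr
    raise ValueError(f"unknown metric {metric!r}")


METRICS = ("power", "exponent", "aec-global", "aec-intra", "aec-inter")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full synthetic-cohort pipeline and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        cohort, series, truth = generate_cohort(config.cohort, config.seed)
        parc = make_parcellation(config.cohort.n_pairs)
        scheme = BandScheme()

        cohort.to_csv(out / "cohort.csv")
        io.write_json(out / "ground_truth.json", truth)

        features = extract_features(series, parc, config, scheme)
        subjects = cohort.subject_ids

        pd.DataFrame(
            [
                {"subject": s, "parcel": parc.labels[i], "band": scheme.names[j],
                 "value": features["power"][s][i, j]}
                for s in subjects
                for i in range(parc.n_parcels)
                for j in range(len(scheme))
            ]
        ).pipe(lambda df: io.write_band_power_csv(out / "band_power.csv", df))
        pd.DataFrame(
            [
                {"subject": s, "parcel": parc.labels[i],
                 "offset": f.offset, "exponent": f.exponent,
                 "n_peaks": f.n_peaks, "r_squared": f.r_squared}
                for s in subjects
                for i, f in enumerate(features["aperiodic_fits"][s])
            ]
        ).pipe(lambda df: io.write_exponent_csv(out / "exponent.csv", df))
        io.write_aec_h5(
            out / "aec.h5",
            {s: {b: features["aec"][s][k] for k, b in enumerate(scheme.names)}
             for s in subjects},
        )
        features["summaries"].to_csv(out / "aec_summaries.csv", index=False)

        glm_results = {}
        for mode in config.glm_modes:
            design = build_design(cohort, mode)
            for metric in METRICS:
                Y = _metric_array(metric, features, subjects, scheme)
                res = permutation_maxt(Y, design, n_perm=config.n_perm, seed=config.seed)
                tag = f"{metric}_{mode}"
                pd.DataFrame(res.t_obs, index=list(parc.labels)).to_csv(out / f"tmap_{tag}.csv")
                pd.DataFrame(res.p_fwe, index=list(parc.labels)).to_csv(out / f"pmap_{tag}.csv")
                glm_results[tag] = {"dof": res.dof, "min_p": float(res.p_fwe.min())}

        prediction = None
        if config.run_prediction:
            table = build_features(
                features["power"], features["exponent"], features["aec"],
                cohort, scheme.names, parc.labels,
            )
            result = nested_loocv(table, config.forest, seed=config.seed)
            pd.DataFrame(
                {"subject": result.subject_ids, "true": result.y_true, "pred": result.y_pred}
            ).to_csv(out / "predictions.csv", index=False)
            prediction = {"r_squared": result.r_squared, "p_value": result.p_value}
            io.write_json(out / "prediction.json", prediction)

        caught = [str(w.message) for w in wlist]

    save_config(out / "config.yaml", config)
    io.write_json(
        out / "manifest.json",
        {
            "seed": config.seed,
            "n_perm": config.n_perm,
            "glm_modes": list(config.glm_modes),
            "glm": glm_results,
            "prediction": prediction,
            "warnings": caught,
        },
    )
    return out
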