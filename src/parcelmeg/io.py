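"""File-format contracts: HDF5 time courses and spectra, tidy metric CSVs.

Every artifact round-trips (write then read returns an equal object) and is
schema-validated on read, with errors naming the missing field.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import PowerSpectrum
from .timeseries import ParcelTimeSeries

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_spectrum",
    "read_spectrum",
    "write_band_power_csv",
    "write_exponent_csv",
    "write_aec_h5",
    "read_aec_h5",
    "write_json",
    "read_json",
]


def write_timeseries(path, ts: ParcelTimeSeries) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("timecourses", data=ts.data)
        d.attrs["fs"] = ts.fs
        d.attrs["subject_id"] = ts.subject_id
        d.attrs["parcels"] = list(ts.parcel_order)


def read_timeseries(path) -> ParcelTimeSeries:
    with h5py.File(path, "r") as f:
        if "timecourses" not in f:
            raise ValueError(f"{path}: missing dataset 'timecourses'")
        d = f["timecourses"]
        for attr in ("fs", "subject_id", "parcels"):
            if attr not in d.attrs:
                raise ValueError(f"{path}: missing attribute {attr!r}")
        return ParcelTimeSeries(
            subject_id=str(d.attrs["subject_id"]),
            data=d[()],
            fs=float(d.attrs["fs"]),
            parcel_order=tuple(str(p) for p in d.attrs["parcels"]),
        )


def write_spectrum(path, spec: PowerSpectrum) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=spec.freqs)
        d = f.create_dataset("psd", data=spec.psd)
        d.attrs["window_s"] = spec.window_s
        d.attrs["fs"] = spec.fs


def read_spectrum(path) -> PowerSpectrum:
    with h5py.File(path, "r") as f:
        for name in ("freqs", "psd"):
            if name not in f:
                raise ValueError(f"{path}: missing dataset {name!r}")
        d = f["psd"]
        for attr in ("window_s", "fs"):
            if attr not in d.attrs:
                raise ValueError(f"{path}: missing attribute {attr!r}")
        return PowerSpectrum(
            freqs=f["freqs"][()],
            psd=d[()],
            window_s=float(d.attrs["window_s"]),
            fs=float(d.attrs["fs"]),
        )


def write_band_power_csv(path, rows: pd.DataFrame) -> None:
    """Tidy band-power table with columns subject, parcel, band, value."""
    required = {"subject", "parcel", "band", "value"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"band power table missing columns: {sorted(missing)}")
    rows.to_csv(path, index=False)


def write_exponent_csv(path, rows: pd.DataFrame) -> None:
    """Tidy aperiodic table: subject, parcel, offset, exponent, n_peaks, r_squared."""
    required = {"subject", "parcel", "offset", "exponent", "n_peaks", "r_squared"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"exponent table missing columns: {sorted(missing)}")
    rows.to_csv(path, index=False)


def write_aec_h5(path, matrices: dict[str, dict[str, np.ndarray]]) -> None:
    """Per-subject groups of band -> parcels x parcels AEC matrices."""
    with h5py.File(path, "w") as f:
        for subject, bands in matrices.items():
            g = f.create_group(subject)
            for band, m in bands.items():
                g.create_dataset(band, data=m)


def read_aec_h5(path) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        for subject in f:
            out[subject] = {band: f[subject][band][()] for band in f[subject]}
    return out


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
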