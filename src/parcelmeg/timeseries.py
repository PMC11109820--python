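"""Parcel-space time-course container."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ParcelTimeSeries"]


@dataclass(frozen=True)
class ParcelTimeSeries:
    """One subject's parcels-by-samples matrix at a known sampling rate.

    ``parcel_order`` pins each row to a parcellation label so downstream
    stages can never silently mis-align rows with anatomy.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    parcel_order: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D parcels x samples matrix")
        if not np.all(np.isfinite(data)):
            raise ValueError("time courses contain non-finite samples")
        if data.shape[0] != len(self.parcel_order):
            raise ValueError(
                f"{data.shape[0]} rows but {len(self.parcel_order)} parcel labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "ParcelTimeSeries":
        return replace(self, data=data, fs=self.fs if fs is None else fs)
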