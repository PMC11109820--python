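"""Leakage correction and amplitude-envelope-correlation connectivity.

Source-reconstructed parcel time courses are linear mixtures of true
sources, so zero-lag leakage inflates connectivity and can create spurious
"ghost interactions" between parcels that share no true source.  Symmetric
multivariate orthogonalization removes all zero-lag linear dependence at
once: it finds the set of mutually uncorrelated time courses closest (in
Frobenius norm) to the originals, treating all parcels symmetrically, by
alternating a closest-orthonormal-matrix (polar decomposition) step with a
per-parcel scaling step.

Connectivity is then the amplitude envelope correlation (AEC): Pearson
correlation between the Hilbert envelopes of band-limited parcel signals,
summarized per parcel as global, intra-hemispheric and inter-hemispheric
means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .parcellation import Parcellation

__all__ = [
    "ConnectivityMatrix",
    "ConnectivitySummary",
    "symmetric_orthogonalize",
    "band_envelope",
    "aec",
    "summarize",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric parcels-by-parcels AEC matrix for one band; diagonal is NaN."""

    band: str
    aec: np.ndarray

    def __post_init__(self) -> None:
        m = self.aec
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("aec must be square")
        off = ~np.eye(m.shape[0], dtype=bool)
        if not np.allclose(m[off], m.T[off]):
            raise ValueError("aec must be symmetric")
        if (np.abs(m[off]) > 1 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class ConnectivitySummary:
    """Per-parcel mean connectivity: global, intra- and inter-hemispheric.

    ``lateralization`` is inter minus intra.  For every parcel the global
    mean is the connection-count-weighted average of intra and inter.
    """

    parcels: tuple[str, ...]
    global_mean: np.ndarray
    intra_mean: np.ndarray
    inter_mean: np.ndarray

    @property
    def lateralization(self) -> np.ndarray:
        return self.inter_mean - self.intra_mean


def symmetric_orthogonalize(
    data: np.ndarray, tol: float = 1e-9, max_iter: int = 100
) -> np.ndarray:
    """Closest set of mutually uncorrelated time courses to ``data``.

    Rows are demeaned first; the solution is then sought in the zero-mean
    subspace, so "orthogonal" and "uncorrelated at lag zero" coincide
    exactly.  The minimizer of ||X - D W||_F over diagonal D > 0 and
    orthonormal-row W alternates:

    * W-step: closest orthonormal matrix to D^{-1}-weighted data via the
      polar decomposition (SVD with singular values replaced by 1);
    * D-step: per-row least-squares scale d_i = <x_i, w_i>.

    Convergence is declared when the relative Frobenius change of the
    reconstruction falls below ``tol``.

    Raises on rank-deficient input (naming the dependent parcels) and on
    non-convergence.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be parcels x samples")
    p, n = X.shape
    if n <= p:
        raise ValueError("need more samples than parcels")
    X = X - X.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the rows most explained by the others
        g = X @ X.T
        d = np.sqrt(np.diag(g))
        c = g / np.outer(d, d)
        np.fill_diagonal(c, 0.0)
        worst = np.argsort(np.abs(c).max(axis=1))[-(p - rank):]
        raise ValueError(
            f"rank-deficient input (rank {rank} < {p}); "
            f"most collinear parcel rows: {sorted(int(i) for i in worst)}"
        )

    d = np.linalg.norm(X, axis=1)
    prev = None
    for _ in range(max_iter):
        # closest orthonormal-rows matrix to diag(1/d)-free target: polar of (D X^T)
        U, _, Vt = np.linalg.svd((X.T * d), full_matrices=False)
        W = (U @ Vt).T  # rows orthonormal
        d = np.einsum("ij,ij->i", X, W)
        O = W * d[:, None]
        change = 1.0 if prev is None else np.linalg.norm(O - prev) / np.linalg.norm(O)
        if prev is not None and change < tol:
            return O
        prev = O
    raise RuntimeError(f"symmetric orthogonalization did not converge in {max_iter} iterations")


def band_envelope(data: np.ndarray, band: tuple[float, float], fs: float, order: int = 5) -> np.ndarray:
    """Zero-phase band-pass then analytic-signal magnitude, per parcel."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    narrow = signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=1)
    return np.abs(signal.hilbert(narrow, axis=1))


def aec(
    envelopes: np.ndarray, band: str = "", edge_trim_s: float = 0.0, fs: float | None = None
) -> ConnectivityMatrix:
    """Pearson correlation between parcel envelope pairs, symmetrized.

    ``edge_trim_s`` seconds are dropped from both ends before correlating
    (Hilbert transforms ring at the edges); requires ``fs`` when nonzero.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.shape[0] < 2:
        raise ValueError("need at least 2 parcels")
    if edge_trim_s > 0:
        if fs is None:
            raise ValueError("fs required when edge_trim_s > 0")
        k = int(round(edge_trim_s * fs))
        if 2 * k >= env.shape[1]:
            raise ValueError("edge trim longer than the data")
        env = env[:, k : env.shape[1] - k]
    if not np.all(np.isfinite(env)):
        raise ValueError("envelopes contain non-finite values")
    if (env.std(axis=1) == 0).any():
        bad = np.flatnonzero(env.std(axis=1) == 0).tolist()
        raise ValueError(f"constant envelope(s) at rows {bad}")
    r = np.corrcoef(env)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, np.nan)
    return ConnectivityMatrix(band=band, aec=r)


def summarize(conn: ConnectivityMatrix, parc: Parcellation) -> ConnectivitySummary:
    """Global / intra- / inter-hemispheric mean connectivity per parcel."""
    m = conn.aec
    if m.shape[0] != parc.n_parcels:
        raise ValueError("matrix dimension does not match parcellation")
    for side in ("left", "right"):
        if len(parc.hemisphere_indices(side)) < 2:
            raise ValueError(f"{side} hemisphere has < 2 parcels: intra-hemispheric mean undefined")
    hemi = np.array(parc.hemisphere)
    same = hemi[:, None] == hemi[None, :]
    off = ~np.eye(parc.n_parcels, dtype=bool)
    vals = np.where(off, m, 0.0)
    n_all = off.sum(axis=1)
    n_intra = (same & off).sum(axis=1)
    n_inter = (~same).sum(axis=1)
    global_mean = (vals * off).sum(axis=1) / n_all
    intra_mean = (vals * (same & off)).sum(axis=1) / n_intra
    inter_mean = (vals * ~same).sum(axis=1) / n_inter
    return ConnectivitySummary(
        parcels=parc.labels,
        global_mean=global_mean,
        intra_mean=intra_mean,
        inter_mean=inter_mean,
    )
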