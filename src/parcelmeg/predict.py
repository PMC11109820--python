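"""Random-forest severity regression under nested leave-one-out CV.

The predictor maps the full per-subject MEG feature set — every pairwise
band-wise envelope correlation, every parcel's band power, and every
parcel's aperiodic exponent — to the change-from-baseline functional score
(48 - ALSFRS-R) in the patient group.  Model selection (greedy forward
stepwise selection scored by k-fold cross-validated R^2, k = 5) is repeated
inside every training fold of an outer leave-one-out loop, so the held-out
subject never influences feature selection or fitting.  Out-of-fold
predictions are pooled and compared against the true scores by linear
regression; the reported R^2 is the squared correlation of true and
predicted values.

A full stepwise search over the ~10^3-10^4 raw features inside every outer
fold is intractable, so candidates are pre-screened within each training
fold to the ``pool_size`` features most correlated (absolute Pearson) with
the training targets.  The screen uses training rows only, preserving the
nested structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

__all__ = [
    "FeatureTable",
    "RandomForestParams",
    "PredictionResult",
    "build_features",
    "stepwise_select",
    "nested_loocv",
]


@dataclass(frozen=True)
class FeatureTable:
    """ALS-subject feature matrix plus the 48 - ALSFRS-R target."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and target length mismatch")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if ((self.y < 0) | (self.y > 48)).any():
            raise ValueError("target must lie in [0, 48]")

    @property
    def n_subjects(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class RandomForestParams:
    """Forest and selection hyper-parameters.

    Defaults: 500 trees, sqrt(p) features per split, unrestricted depth;
    inner k = 5 folds; candidate pool of 50 pre-screened features.
    ``selection_estimators`` optionally uses a smaller forest while scoring
    candidate subsets in the stepwise search (the per-fold final model always
    uses ``n_estimators``); selection only ranks subsets, so it tolerates a
    noisier score.
    """

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    k: int = 5
    pool_size: int = 50
    selection_estimators: int | None = None

    @property
    def n_selection(self) -> int:
        return self.selection_estimators or self.n_estimators


@dataclass(frozen=True)
class PredictionResult:
    """Pooled out-of-fold predictions and their regression summary.

    ``r_squared``/``p_value`` come from the linear regression of true on
    predicted values (so ``r_squared`` equals the squared Pearson
    correlation); ``r2_oof`` is the out-of-fold coefficient of
    determination, 1 - SS_res/SS_tot, which unlike the squared correlation
    is negative when predictions are worse than the mean — the quantity to
    inspect when checking that a model has learned nothing.
    """

    subject_ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    r_squared: float
    p_value: float
    r2_oof: float
    selected: tuple[tuple[str, ...], ...]


def build_features(
    power: dict[str, np.ndarray],
    exponent: dict[str, np.ndarray],
    aec_mats: dict[str, np.ndarray],
    cohort,
    bands: tuple[str, ...],
    parcels: tuple[str, ...],
) -> FeatureTable:
    """Assemble the feature table for the ALS subjects.

    ``power[s]`` is parcels x bands, ``exponent[s]`` a parcel vector and
    ``aec_mats[s]`` bands x parcels x parcels per subject id ``s``.  Column
    order is deterministic: AEC pairs band-major then pair-lexicographic,
    then band power band-major, then exponents.
    """
    df = cohort.df
    als = df[df["group"] == "ALS"]
    subjects = als["subject_id"].tolist()
    missing = [
        s
        for s in subjects
        if s not in power or s not in exponent or s not in aec_mats
    ]
    if missing:
        raise ValueError(f"subjects missing metric data: {missing}")
    P = len(parcels)
    iu = np.triu_indices(P, k=1)
    columns = (
        [f"aec|{b}|{parcels[i]}--{parcels[j]}" for b in bands for i, j in zip(*iu)]
        + [f"power|{b}|{p}" for b in bands for p in parcels]
        + [f"exponent|{p}" for p in parcels]
    )
    rows = []
    for s in subjects:
        a = aec_mats[s]
        pw = power[s]
        ex = exponent[s]
        if a.shape != (len(bands), P, P) or pw.shape != (P, len(bands)) or ex.shape != (P,):
            raise ValueError(f"metric shape mismatch for subject {s}")
        rows.append(
            np.concatenate(
                [a[b][iu] for b in range(len(bands))]
                + [pw[:, b] for b in range(len(bands))]
                + [ex]
            )
        )
    X = pd.DataFrame(rows, index=subjects, columns=columns)
    y = pd.Series(
        48.0 - als.set_index("subject_id").loc[subjects, "alsfrs_r"].to_numpy(dtype=float),
        index=subjects,
        name="alsfrs_change",
    )
    return FeatureTable(X=X, y=y)


def _cv_r2(
    X: np.ndarray, y: np.ndarray, cols: list[int], params: RandomForestParams, seed: int
) -> float:
    """Pooled out-of-fold R^2 of the forest on the given feature subset."""
    kf = KFold(n_splits=params.k, shuffle=True, random_state=seed % (2**31))
    pred = np.empty_like(y)
    for tr, te in kf.split(X):
        rf = RandomForestRegressor(
            n_estimators=params.n_selection,
            max_features=params.max_features,
            random_state=seed % (2**31),
            n_jobs=1,
        )
        rf.fit(X[np.ix_(tr, cols)], y[tr])
        pred[te] = rf.predict(X[np.ix_(te, cols)])
    return r2_score(y, pred)


def stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    params: RandomForestParams = RandomForestParams(),
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection maximizing inner k-fold CV R^2.

    Candidates are the ``pool_size`` columns most correlated with ``y`` in
    the provided (training) data.  Selection stops at the first addition
    that fails to improve the CV score; ties break toward the earlier
    column.  At least one feature is always returned.
    """
    if len(X) < params.k:
        raise ValueError(f"need at least k = {params.k} training rows, got {len(X)}")
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(
            ((Xv - Xv.mean(0)) * (y - y.mean())[:, None]).mean(0) / (sd * y.std() + 1e-300)
        )
    corr[sd == 0] = 0.0
    pool = list(np.argsort(-corr, kind="stable")[: params.pool_size])

    selected: list[int] = []
    best = -np.inf
    while pool:
        scores = [
            (_cv_r2(Xv, y, selected + [c], params, seed), -i, c)
            for i, c in enumerate(pool)
        ]
        score, _, c = max(scores)
        if score <= best:
            break
        selected.append(c)
        pool.remove(c)
        best = score
    return [X.columns[c] for c in selected]


def nested_loocv(
    features: FeatureTable,
    params: RandomForestParams = RandomForestParams(),
    seed: int = 0,
) -> PredictionResult:
    """Leave-one-out outer loop with per-fold stepwise selection.

    Each subject is predicted by a forest trained (and feature-selected)
    exclusively on the other n - 1 subjects.  Deterministic under ``seed``:
    per-fold seeds are derived by offsetting the master seed.
    """
    n = features.n_subjects
    if n < 10:
        raise ValueError(f"need at least 10 subjects for nested LOOCV, got {n}")
    y = features.y.to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("constant target: nothing to predict")
    X = features.X
    preds = np.empty(n)
    logs: list[tuple[str, ...]] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        fold_seed = (seed * 100003 + i) % (2**31)
        cols = stepwise_select(X.iloc[tr], y[tr], params, seed=fold_seed)
        rf = RandomForestRegressor(
            n_estimators=params.n_estimators,
            max_features=params.max_features,
            random_state=fold_seed,
            n_jobs=1,
        )
        rf.fit(X.iloc[tr][cols].to_numpy(dtype=float), y[tr])
        preds[i] = rf.predict(X.iloc[[i]][cols].to_numpy(dtype=float))[0]
        logs.append(tuple(cols))
    if np.std(preds) == 0:
        r2, p = 0.0, 1.0
    else:
        fit = stats.linregress(preds, y)
        r2, p = float(fit.rvalue**2), float(fit.pvalue)
    return PredictionResult(
        subject_ids=tuple(features.X.index),
        y_true=y,
        y_pred=preds,
        r_squared=r2,
        p_value=p,
        r2_oof=float(r2_score(y, preds)),
        selected=tuple(logs),
    )
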