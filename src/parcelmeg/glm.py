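"""Permutation-based general linear model with max-statistic FWE control.

Each parcel-by-band metric is summarized by a separate ordinary-least-squares
GLM whose regressors of interest are either two group indicators (ALS,
control) or a single clinical-score column with controls fixed at 0, always
alongside confound regressors for age, sex and handedness.  Family-wise
error across all parcels and bands is controlled non-parametrically: the
rows of the interest regressors are permuted (confounds stay fixed), the
models are refitted, and the maximum |t| across all cells per permutation
forms the null distribution against which each observed |t| is compared.
An observed statistic more extreme than 95% of the null maxima therefore
receives a corrected P of 0.05 (up to the +1 finite-sample correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable

__all__ = [
    "DesignMatrix",
    "PermutationResult",
    "build_design",
    "fit_glm",
    "permutation_maxt",
    "max_stat_pvalues",
    "format_t",
]

DESIGN_MODES = ("group", "alsfrs_change", "umn", "delta_alsfrs")


@dataclass(frozen=True)
class DesignMatrix:
    """Subjects-by-regressors design with a contrast over the columns.

    ``interest`` indexes the columns whose rows are exchanged under the
    permutation null; confound columns never move.
    """

    X: np.ndarray
    columns: tuple[str, ...]
    contrast: np.ndarray
    interest: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        if len(self.contrast) != self.X.shape[1]:
            raise ValueError("contrast length does not match design columns")
        if (np.abs(self.X).sum(axis=0) == 0).any():
            raise ValueError("design contains an all-zero column")
        for j, c in enumerate(self.contrast):
            if c != 0 and j not in self.interest:
                raise ValueError("contrast must be zero on confound columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class PermutationResult:
    """Observed t-map, permutation null of maxima, and FWE-corrected p-map."""

    t_obs: np.ndarray
    dof: int
    null_max: np.ndarray
    p_fwe: np.ndarray
    n_perm: int


def build_design(cohort: CohortTable, mode: str) -> DesignMatrix:
    """Build the design for one analysis mode.

    ``group``: ALS and control indicator columns plus centered age/sex/
    handedness confounds; two-tailed ALS - control contrast.  Score modes
    (``alsfrs_change`` = 48 - ALSFRS-R, ``umn``, ``delta_alsfrs``): the score
    column (controls at 0) plus an intercept and the same confounds, with
    the contrast on the score column.
    """
    if mode not in DESIGN_MODES:
        raise ValueError(f"unknown design mode {mode!r}; expected one of {DESIGN_MODES}")
    df = cohort.df
    for col in ("age", "sex", "handedness"):
        bad = df.loc[df[col].isna(), "subject_id"].tolist()
        if bad:
            raise ValueError(f"missing {col} for subjects: {bad}")
    age = df["age"].to_numpy(dtype=float)
    sex = np.where(df["sex"] == "M", 0.5, -0.5)
    hand = np.where(df["handedness"] == "right", 0.5, -0.5)
    confounds = np.column_stack([age - age.mean(), sex - sex.mean(), hand - hand.mean()])
    conf_names = ("age", "sex", "handedness")
    # a covariate constant across the cohort (e.g. everyone right-handed)
    # carries no confound information once centered; drop it
    keep = confounds.std(axis=0) > 0
    confounds = confounds[:, keep]
    conf_names = tuple(n for n, k in zip(conf_names, keep) if k)

    if mode == "group":
        als = cohort.is_als.astype(float)
        X = np.column_stack([als, 1.0 - als, confounds])
        names = ("ALS", "control") + conf_names
        contrast = np.concatenate([[1.0, -1.0], np.zeros(confounds.shape[1])])
        interest = (0, 1)
    else:
        score = cohort.clinical_score(mode)
        if score.std() == 0:
            raise ValueError(f"degenerate contrast: {mode} score is constant")
        X = np.column_stack([score, np.ones(len(df)), confounds])
        names = (mode, "intercept") + conf_names
        contrast = np.concatenate([[1.0, 0.0], np.zeros(confounds.shape[1])])
        interest = (0,)
    return DesignMatrix(X=X, columns=names, contrast=contrast, interest=interest)


def _t_stats(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, int]:
    """Contrast t-statistics for every column of Y under one design."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {k} columns)")
    dof = n - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    var_c = float(contrast @ xtx_inv @ contrast)
    se = np.sqrt(sigma2 * var_c)
    effect = contrast @ beta
    # residual variance at floating-point noise level: the fit is exact and
    # the t-statistic is flagged infinite rather than reported as a huge
    # finite number
    scale = np.maximum((Y**2).mean(axis=0), 1e-300)
    degenerate = sigma2 <= 1e-20 * scale
    null_effect = np.abs(effect) <= 1e-10 * np.sqrt(scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            degenerate,
            np.where(null_effect, 0.0, np.inf * np.sign(effect)),
            effect / np.where(se > 0, se, 1.0),
        )
    return t, dof


def fit_glm(y: np.ndarray, design: DesignMatrix) -> tuple[float, int]:
    """OLS contrast t-statistic and residual dof for a single outcome vector."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != design.n:
        raise ValueError("y must be a vector with one value per subject")
    t, dof = _t_stats(y[:, None], design.X, design.contrast)
    return float(t[0]), dof


def permutation_maxt(
    Y: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 5000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-tailed max-|t| permutation inference over a parcels-by-bands map.

    ``Y`` is subjects x parcels x bands (a trailing band axis of size 1 is
    fine).  Per permutation the rows of the interest regressors are jointly
    shuffled, every cell's GLM refitted, and the maximum |t| recorded;
    p_fwe(cell) = (1 + #{null_max >= |t_obs|}) / (n_perm + 1), ties counting
    toward the null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100: p-value resolution too coarse")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    if Y.ndim != 3 or Y.shape[0] != design.n:
        raise ValueError("Y must be subjects x parcels x bands")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    n, p, b = Y.shape
    flat = Y.reshape(n, p * b)
    t_obs, dof = _t_stats(flat, design.X, design.contrast)

    rng = np.random.default_rng(seed)
    interest = list(design.interest)
    null_max = np.empty(n_perm)
    Xp = design.X.copy()
    for i in range(n_perm):
        perm = rng.permutation(n)
        Xp[:, interest] = design.X[np.ix_(perm, interest)]
        t_perm, _ = _t_stats(flat, Xp, design.contrast)
        null_max[i] = np.abs(t_perm).max()

    p_fwe = max_stat_pvalues(t_obs, null_max).reshape(p, b)
    return PermutationResult(
        t_obs=t_obs.reshape(p, b),
        dof=dof,
        null_max=null_max,
        p_fwe=p_fwe,
        n_perm=n_perm,
    )


def max_stat_pvalues(t_obs: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """FWE-corrected p-values from a null distribution of maximum statistics.

    p = (1 + #{null_max >= |t_obs|}) / (n_perm + 1): an observed statistic
    more extreme than 95% of the null maxima receives p = 0.05 up to the +1
    finite-sample correction, and p is never exactly 0.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    null_max = np.asarray(null_max, dtype=float)
    n_perm = null_max.size
    exceed = (null_max[None, :] >= np.abs(t_obs).ravel()[:, None]).sum(axis=1)
    return ((1.0 + exceed) / (n_perm + 1.0)).reshape(t_obs.shape)


def format_t(t: float, dof: int) -> str:
    """Report a statistic in the t(DOF) convention, e.g. ``t(82) = 3.73``."""
    return f"t({dof}) = {t:.3f}"
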