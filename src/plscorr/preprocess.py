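"""Normalization of the two blocks and the cross-block correlation matrix.

Brain columns are residualized on age with per-column simple linear
regressions; both blocks are then z-scored column-wise (sample SD, n-1).
All fitting parameters live in a :class:`PreprocessModel` so train-fitted
parameters can be applied to held-out subjects without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import StudyDataset


@dataclass
class PreprocessModel:
    """Fitted normalization parameters (age regression + column z-scoring)."""

    age_intercept: np.ndarray | None = None  # (p,)
    age_slope: np.ndarray | None = None  # (p,)
    x_mean: np.ndarray | None = None  # (p,)
    x_sd: np.ndarray | None = None  # (p,)
    y_mean: np.ndarray | None = None  # (q,)
    y_sd: np.ndarray | None = None  # (q,)


@dataclass
class CrossCorrelation:
    """Pearson correlation of every brain column with every behavior column."""

    R: np.ndarray  # (p, q)
    n_subjects: int


def fit_age_regression(brain: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares intercept and slope of each brain column on age."""
    brain = np.asarray(brain, float)
    age = np.asarray(age, float)
    if brain.shape[0] < 3:
        raise ValueError("need at least 3 subjects to fit the age regression")
    a_c = age - age.mean()
    denom = a_c @ a_c
    if denom == 0:
        raise ValueError("age has zero variance on the fitting subset")
    slope = (a_c @ (brain - brain.mean(axis=0))) / denom
    intercept = brain.mean(axis=0) - slope * age.mean()
    return intercept, slope


def apply_age_regression(
    brain: np.ndarray, age: np.ndarray, intercept: np.ndarray, slope: np.ndarray
) -> np.ndarray:
    return np.asarray(brain, float) - (intercept + np.outer(np.asarray(age, float), slope))


def residualize_age(
    ds: StudyDataset, fit_on: np.ndarray | None = None
) -> tuple[np.ndarray, PreprocessModel]:
    """Replace each brain column with its residual from a regression on age.

    The regression is fit on the subjects selected by ``fit_on`` (boolean or
    index array; default all subjects) and applied to every subject in
    ``ds``. The behavior block is untouched — only the brain block is
    age-corrected.
    """
    if fit_on is None:
        fit_on = np.ones(ds.n, dtype=bool)
    brain_fit = ds.brain[fit_on]
    age_fit = ds.age[fit_on]
    intercept, slope = fit_age_regression(brain_fit, age_fit)
    resid = apply_age_regression(ds.brain, ds.age, intercept, slope)
    model = PreprocessModel(age_intercept=intercept, age_slope=slope)
    return resid, model


def zscore_columns(
    X: np.ndarray,
    params: tuple[np.ndarray, np.ndarray] | None = None,
    *,
    names: list[str] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-wise z-scoring with sample SD (denominator n-1).

    With ``params=None`` the mean/SD are fitted on ``X`` itself; otherwise
    the given ``(mean, sd)`` are applied (train-to-test transfer). Returns
    the transformed matrix and the parameters used.
    """
    X = np.asarray(X, float)
    if params is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        # relative threshold: a numerically-constant column (e.g. all 4.2)
        # has sd ~ 1e-16, not exactly 0
        zero = np.nonzero(sd <= 1e-12 * np.maximum(np.abs(mean), 1.0))[0]
        if zero.size:
            label = names[zero[0]] if names else f"index {zero[0]}"
            raise ValueError(f"zero-variance column ({label}) cannot be z-scored")
    else:
        mean, sd = (np.asarray(a, float) for a in params)
        if np.any(sd == 0):
            raise ValueError("stored z-scoring SD contains zeros")
    return (X - mean) / sd, (mean, sd)


def fit_preprocess(
    ds: StudyDataset,
    fit_on: np.ndarray | None = None,
    *,
    age_correct: bool = True,
) -> tuple[np.ndarray, np.ndarray, PreprocessModel]:
    """Full normalization: age-residualize brain, z-score both blocks.

    Fitting (age regression, means, SDs) uses only the ``fit_on`` subjects;
    the transform is applied to all subjects in ``ds``. Returns
    ``(Zx, Zy, model)``. ``age_correct=False`` skips the age regression
    (for imaging inputs that are not age-corrected).
    """
    if fit_on is None:
        fit_on = np.ones(ds.n, dtype=bool)
    if age_correct:
        resid, model = residualize_age(ds, fit_on)
    else:
        resid, model = ds.brain, PreprocessModel()
    _, (xm, xs) = zscore_columns(resid[fit_on], names=ds.roi_names)
    Zx, _ = zscore_columns(resid, (xm, xs))
    _, (ym, ys) = zscore_columns(ds.behavior[fit_on], names=ds.behavior_names)
    Zy, _ = zscore_columns(ds.behavior, (ym, ys))
    model.x_mean, model.x_sd = xm, xs
    model.y_mean, model.y_sd = ym, ys
    return Zx, Zy, model


def apply_preprocess(ds: StudyDataset, model: PreprocessModel) -> tuple[np.ndarray, np.ndarray]:
    """Apply an already-fitted model to (held-out) subjects."""
    if model.age_intercept is not None:
        resid = apply_age_regression(ds.brain, ds.age, model.age_intercept, model.age_slope)
    else:
        resid = ds.brain
    Zx, _ = zscore_columns(resid, (model.x_mean, model.x_sd))
    Zy, _ = zscore_columns(ds.behavior, (model.y_mean, model.y_sd))
    return Zx, Zy


def cross_correlation(Zx: np.ndarray, Zy: np.ndarray) -> CrossCorrelation:
    """Pearson correlation of each brain column with each behavior column.

    The inputs need not be pre-standardized; correlations are computed on
    the columns as given (so they are invariant to any affine rescaling).
    """
    Zx = np.asarray(Zx, float)
    Zy = np.asarray(Zy, float)
    if Zx.shape[0] != Zy.shape[0]:
        raise ValueError(f"blocks have different n: {Zx.shape[0]} vs {Zy.shape[0]}")
    n = Zx.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for correlations")
    xc = Zx - Zx.mean(axis=0)
    yc = Zy - Zy.mean(axis=0)
    xs = np.sqrt((xc**2).sum(axis=0))
    ys = np.sqrt((yc**2).sum(axis=0))
    if np.any(xs == 0) or np.any(ys == 0):
        raise ValueError("zero-variance column in correlation input")
    R = (xc.T @ yc) / np.outer(xs, ys)
    return CrossCorrelation(R=np.clip(R, -1.0, 1.0), n_subjects=n)


def effective_rank(
    C: np.ndarray, method: str = "eigenvalue_variance"
) -> tuple[float, int]:
    """Effective number of independent variables from a correlation matrix.

    ``eigenvalue_variance`` (default): with eigenvalues λ of the M×M matrix,
    Meff = 1 + (M-1) * (1 - Var(λ)/M), Var using denominator M-1.
    ``truncated``: sum over eigenvalues of 1[λ >= 1] + (λ - floor(λ)).
    Returns the real value and its floor.
    """
    C = np.asarray(C, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    M = C.shape[0]
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)  # guard non-PSD numerical noise
    if method == "eigenvalue_variance":
        if M == 1:
            meff = 1.0
        else:
            var = lam.var(ddof=1)
            meff = 1.0 + (M - 1) * (1.0 - var / M)
    elif method == "truncated":
        meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    else:
        raise ValueError(f"unknown method {method!r}")
    meff = float(np.clip(meff, 1.0, M))
    return meff, int(np.floor(meff))
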