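"""SVD of the cross-correlation matrix into latent variables (LVs).

Each LV pairs a brain weight vector (left singular vector), a behavior
weight vector (right singular vector), and a singular value. Subject scores
are projections of the z-scored blocks onto the weights; loadings are
Pearson correlations of each original column with its own block's scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import CrossCorrelation


@dataclass
class PlsDecomposition:
    U: np.ndarray  # (p, k) brain weights
    V: np.ndarray  # (q, k) behavior weights
    S: np.ndarray  # (k,) singular values, descending
    covexp: np.ndarray  # (k,) fractions of squared singular values
    brain_scores: np.ndarray  # (n, k) = Zx @ U
    behavior_scores: np.ndarray  # (n, k) = Zy @ V
    brain_loadings: np.ndarray  # (p, k)
    behavior_loadings: np.ndarray  # (q, k)
    roi_names: list[str] | None = None
    behavior_names: list[str] | None = None

    @property
    def k(self) -> int:
        return self.S.shape[0]


def covariance_explained(S: np.ndarray) -> np.ndarray:
    """Fraction of cross-block covariance captured per LV: S_i^2 / sum S^2."""
    S = np.asarray(S, float)
    if np.any(S < 0):
        raise ValueError("singular values must be non-negative")
    total = float(np.sum(S**2))
    if total == 0:
        raise ValueError("all singular values are zero")
    return S**2 / total


def column_correlations(Z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of Z with every column of scores."""
    Zc = Z - Z.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    zn = np.sqrt((Zc**2).sum(axis=0))
    sn = np.sqrt((Sc**2).sum(axis=0))
    zn = np.where(zn == 0, np.nan, zn)
    sn = np.where(sn == 0, np.nan, sn)
    return np.clip((Zc.T @ Sc) / np.outer(zn, sn), -1.0, 1.0)


def decompose(
    R: CrossCorrelation | np.ndarray,
    Zx: np.ndarray,
    Zy: np.ndarray,
    *,
    roi_names: list[str] | None = None,
    behavior_names: list[str] | None = None,
) -> PlsDecomposition:
    """Full SVD of the cross-correlation matrix, with scores and loadings.

    Sign convention: each (u_i, v_i) pair is flipped jointly so that the
    behavior loading largest in absolute value is positive. Joint flipping
    leaves the brain-behavior score correlation unchanged, so results are
    deterministic without altering the fit.
    """
    Rm = R.R if isinstance(R, CrossCorrelation) else np.asarray(R, float)
    Zx = np.asarray(Zx, float)
    Zy = np.asarray(Zy, float)
    if Rm.shape != (Zx.shape[1], Zy.shape[1]):
        raise ValueError("R shape does not match block column counts")
    if not np.any(Rm):
        raise ValueError("no covariance structure: R is all zeros")

    U, S, Vt = np.linalg.svd(Rm, full_matrices=False)
    V = Vt.T

    brain_scores = Zx @ U
    behavior_scores = Zy @ V
    behavior_loadings = column_correlations(Zy, behavior_scores)

    # joint sign flip per LV keyed on the dominant behavior loading
    with np.errstate(invalid="ignore"):
        key = np.nanargmax(np.abs(behavior_loadings), axis=0)
    flip = np.sign(behavior_loadings[key, np.arange(V.shape[1])])
    flip = np.where(flip == 0, 1.0, flip)
    U = U * flip
    V = V * flip
    brain_scores = brain_scores * flip
    behavior_scores = behavior_scores * flip

    return PlsDecomposition(
        U=U,
        V=V,
        S=S,
        covexp=covariance_explained(S),
        brain_scores=brain_scores,
        behavior_scores=behavior_scores,
        brain_loadings=column_correlations(Zx, brain_scores),
        behavior_loadings=column_correlations(Zy, behavior_scores),
        roi_names=roi_names,
        behavior_names=behavior_names,
    )


def project_scores(
    Zx_new: np.ndarray,
    Zy_new: np.ndarray,
    dec: PlsDecomposition,
    lv: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project (held-out) normalized blocks onto the fitted weights.

    ``Zx_new``/``Zy_new`` must be normalized with the *train*-fitted
    preprocessing model. With ``lv`` given, returns the two score vectors
    for that LV (0-based); otherwise all k columns.
    """
    Zx_new = np.atleast_2d(np.asarray(Zx_new, float))
    Zy_new = np.atleast_2d(np.asarray(Zy_new, float))
    if Zx_new.shape[1] != dec.U.shape[0]:
        raise ValueError(
            f"brain block has {Zx_new.shape[1]} columns, expected {dec.U.shape[0]}"
        )
    if Zy_new.shape[1] != dec.V.shape[0]:
        raise ValueError(
            f"behavior block has {Zy_new.shape[1]} columns, expected {dec.V.shape[0]}"
        )
    if lv is None:
        return Zx_new @ dec.U, Zy_new @ dec.V
    return Zx_new @ dec.U[:, lv], Zy_new @ dec.V[:, lv]


def score_correlation(
    brain_scores: np.ndarray, behavior_scores: np.ndarray
) -> tuple[float, float]:
    """Pearson r between the two score vectors with two-sided parametric p."""
    x = np.asarray(brain_scores, float).ravel()
    y = np.asarray(behavior_scores, float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("score vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a score vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
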