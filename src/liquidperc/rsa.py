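"""Representational dissimilarity matrices and their comparison.

Two distance conventions are used: Euclidean distance (unit-level analysis
and all single-value high-level predictors — correlation distance is
undefined for units that never activate) and 1 - Pearson correlation
(layer-level analysis).  RDMs are compared by Spearman rank correlation of
their strict upper triangles, and explained by ordinary least squares
regression on predictor RDMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "RDM",
    "RDMComparison",
    "rdm_from_features",
    "compare_rdms",
    "rdm_regression",
    "predictor_intercorrelation",
    "upper_triangle",
]


@dataclass
class RDM:
    """n x n symmetric dissimilarity matrix over stimuli."""

    values: np.ndarray
    metric: str                       # "euclidean" | "one_minus_pearson"
    stimulus_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        self.values = v
        if self.stimulus_ids is None:
            self.stimulus_ids = np.arange(v.shape[0])
        else:
            self.stimulus_ids = np.asarray(self.stimulus_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def triangle(self) -> np.ndarray:
        return upper_triangle(self.values)


@dataclass(frozen=True)
class RDMComparison:
    spearman_r: float
    n_pairs: int


def upper_triangle(mat: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major order."""
    i, j = np.triu_indices(mat.shape[0], k=1)
    return np.asarray(mat)[i, j]


def rdm_from_features(features: np.ndarray, metric: str = "euclidean",
                      stimulus_ids: np.ndarray | None = None) -> RDM:
    """Pairwise dissimilarities from per-stimulus feature arrays.

    ``features``: (n_stimuli, ...) — multi-dimensional features are
    flattened before the distance.  Under ``one_minus_pearson``, stimuli
    with constant feature vectors yield undefined correlations; those
    pairs are set to NaN with a warning and excluded downstream.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("an RDM needs at least two stimuli")
    X = X.reshape(X.shape[0], -1)
    if metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif metric == "one_minus_pearson":
        sd = X.std(axis=1)
        const = sd == 0
        if np.any(const):
            warnings.warn(f"{const.sum()} stimuli have constant features; "
                          "their correlation distances are undefined (NaN)")
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.corrcoef(X)
        d[const, :] = np.nan
        d[:, const] = np.nan
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown RDM metric {metric!r}")
    return RDM(values=d, metric=metric, stimulus_ids=stimulus_ids)


def _check_aligned(a: RDM, b: RDM) -> None:
    if a.n != b.n or not np.array_equal(a.stimulus_ids, b.stimulus_ids):
        raise ValueError("RDMs are not on the same stimulus registry")


def compare_rdms(a: RDM, b: RDM) -> RDMComparison:
    """Spearman rank correlation over the strict upper triangles
    (average-rank tie handling); NaN pairs are excluded."""
    _check_aligned(a, b)
    x, y = a.triangle(), b.triangle()
    ok = np.isfinite(x) & np.isfinite(y)
    r = spearmanr(x[ok], y[ok]).statistic
    return RDMComparison(spearman_r=float(r), n_pairs=int(ok.sum()))


def rdm_regression(target: RDM, predictors: "list[RDM]") -> float:
    """OLS R-squared of the target RDM's upper triangle on the predictors'.

    Rank-deficient (collinear) predictor sets trigger a warning and are
    solved by pseudo-inverse.
    """
    if not predictors:
        raise ValueError("need at least one predictor RDM")
    for p in predictors:
        _check_aligned(target, p)
    y = target.triangle()
    X = np.column_stack([p.triangle() for p in predictors])
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    A = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        warnings.warn("collinear predictor RDMs; using pseudo-inverse solution")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(1.0 - np.sum(resid ** 2) / ss_tot)


def predictor_intercorrelation(rdms: "list[RDM]") -> np.ndarray:
    """Symmetric Spearman matrix between predictor RDMs (unit diagonal)."""
    k = len(rdms)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = compare_rdms(rdms[i], rdms[j]).spearman_r
            out[i, j] = out[j, i] = r
    return out
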