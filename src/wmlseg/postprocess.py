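"""Probability-to-mask conversion, lesion filtering, WMLV and severity rating.

A predicted probability volume becomes a final lesion mask in two
steps: pixels with probability strictly above 0.5 become candidates,
then connected components are dropped when they contain fewer than five
pixels or fall outside white matter (component-wise WM probability
below 0.4). White matter lesion volume (WMLV, ml) is the surviving
voxel count times the voxel volume. The 0-9 severity score is obtained
by substituting WMLV into a linear regression fitted on training
subjects (score = slope * WMLV + intercept), rounded and clamped to the
scale.

Components are defined per-slice with 8-connectivity by default,
matching the slice-wise network; full 3D 26-connectivity is available
via the ``connectivity`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import AlignmentError, DegenerateDesignError, GeometryError, InvalidVolumeError

__all__ = [
    "LesionComponent",
    "RatingModel",
    "label_components",
    "threshold_probabilities",
    "filter_lesions",
    "compute_wmlv",
    "fit_rating_model",
    "predict_score",
    "WmlvRatingRegressor",
]

_WM_STATS = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass(frozen=True)
class LesionComponent:
    label: int
    pixel_count: int
    indices: tuple  # np.where-style index tuple into the volume
    wm_probability: float | None = None


@dataclass(frozen=True)
class RatingModel:
    """Linear WMLV -> score map with clamping to the rating scale."""

    slope: float
    intercept: float
    clamp: tuple[int, int] = (0, 9)


def _structure(ndim: int, connectivity: str) -> np.ndarray:
    if ndim == 2:
        return np.ones((3, 3), dtype=bool)  # in-plane 8-connectivity
    if connectivity == "2d8":
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1] = True  # neighbours within one slice only
        return s
    if connectivity == "3d26":
        return np.ones((3, 3, 3), dtype=bool)
    raise ValueError(f"unknown connectivity '{connectivity}'")


def label_components(mask: np.ndarray, connectivity: str = "2d8") -> tuple[np.ndarray, int]:
    """Label connected lesion components (per-slice 8-connected by default)."""
    mask = np.asarray(mask).astype(bool)
    return ndimage.label(mask, structure=_structure(mask.ndim, connectivity))


def threshold_probabilities(prob: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Candidate lesion mask: probability strictly greater than tau."""
    return np.asarray(prob) > tau


def filter_lesions(
    mask: np.ndarray,
    wm_probability: np.ndarray,
    min_pixels: int = 5,
    wm_tau: float = 0.4,
    connectivity: str = "2d8",
    wm_statistic: str = "mean",
) -> np.ndarray:
    """Remove small and extra-white-matter components from a candidate mask.

    A component survives iff it has at least ``min_pixels`` pixels and
    its WM-membership statistic (default: mean WM probability over its
    voxels) is at least ``wm_tau``. Surviving voxels are unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    wm_probability = np.asarray(wm_probability)
    if mask.shape != wm_probability.shape:
        raise AlignmentError("mask and WM probability map are not aligned")
    if wm_statistic not in _WM_STATS:
        raise ValueError(f"unknown wm_statistic '{wm_statistic}'")
    labels, n = label_components(mask, connectivity)
    if n == 0:
        return mask
    index = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(mask, labels, index=index)
    agg = {"mean": ndimage.mean, "median": ndimage.median, "max": ndimage.maximum}[wm_statistic]
    wm_stat = np.asarray(agg(wm_probability, labels, index=index))
    keep = index[(sizes >= min_pixels) & (wm_stat >= wm_tau)]
    return np.isin(labels, keep)


def components(
    mask: np.ndarray, wm_probability: np.ndarray | None = None, connectivity: str = "2d8"
) -> list[LesionComponent]:
    """Enumerate connected components with sizes and WM membership."""
    labels, n = label_components(mask, connectivity)
    out = []
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)
        wm = float(np.mean(wm_probability[idx])) if wm_probability is not None else None
        out.append(LesionComponent(lab, len(idx[0]), idx, wm))
    return out


def compute_wmlv(mask: np.ndarray, pixel_spacing: tuple[float, float], slice_thickness: float) -> float:
    """Lesion volume in ml: foreground voxel count x voxel volume / 1000."""
    sr, sc = pixel_spacing
    if sr <= 0 or sc <= 0 or slice_thickness <= 0:
        raise GeometryError("voxel geometry must be positive")
    count = int(np.count_nonzero(mask))
    return count * sr * sc * slice_thickness / 1000.0


def fit_rating_model(train_wmlv, train_scores, clamp: tuple[int, int] = (0, 9)) -> RatingModel:
    """OLS of score on WMLV over training subjects."""
    wmlv = np.asarray(train_wmlv, dtype=float)
    scores = np.asarray(train_scores, dtype=float)
    if wmlv.shape != scores.shape:
        raise ValueError("wmlv and scores must have equal length")
    if wmlv.size < 2 or np.unique(wmlv).size < 2:
        raise DegenerateDesignError("need >= 2 distinct WMLV values to fit the rating line")
    fit = stats.linregress(wmlv, scores)
    return RatingModel(slope=float(fit.slope), intercept=float(fit.intercept), clamp=clamp)


def predict_score(model: RatingModel, wmlv: float) -> tuple[float, int]:
    """Continuous and rounded-clamped integer score for a measured WMLV."""
    if wmlv < 0:
        raise InvalidVolumeError(f"negative WMLV {wmlv}")
    cont = model.slope * wmlv + model.intercept
    lo, hi = model.clamp
    integer = int(np.clip(np.round(cont), lo, hi))
    return float(cont), integer


class WmlvRatingRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the WMLV -> 0-9 severity rating.

    ``fit`` expects WMLV in ml (shape (n,) or (n, 1)) and the observer
    scores; ``predict`` returns continuous scores, ``predict_rating``
    the rounded, clamped integers used for reporting.
    """

    def __init__(self, clamp: tuple[int, int] = (0, 9)):
        self.clamp = clamp

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        model = fit_rating_model(X, y, clamp=self.clamp)
        self.slope_ = model.slope
        self.intercept_ = model.intercept
        self.model_ = model
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * X + self.intercept_

    def predict_rating(self, X) -> np.ndarray:
        cont = self.predict(X)
        return np.clip(np.round(cont), *self.clamp).astype(int)
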