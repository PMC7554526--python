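"""Geometry and intensity normalisation and informative-slice selection.

Three steps prepare a subject for the slice-wise network: (1) every
slice is brought to a uniform in-plane size (default 256 x 256) by
centre-cropping larger matrices and symmetrically zero-padding smaller
ones; (2) slices containing no white matter, grey matter or CSF (by the
tissue probability maps) are discarded; (3) each modality volume is
linearly rescaled so its global minimum maps to 0 and maximum to 255.

Crop/pad is pure index arithmetic (no interpolation), so binary masks
and probability maps pass through it unchanged in value. When the size
difference is odd, the extra row/column is taken from or added to the
trailing edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, NoBrainContentError

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectVolumes",
    "TissueMaps",
    "normalize_size",
    "select_slices",
    "normalize_intensity",
    "preprocess_subject",
]


@dataclass
class SubjectVolumes:
    """Co-registered FLAIR and DWI stacks with voxel geometry.

    Arrays are (slices, rows, cols); pixel_spacing is (row, col) in mm.
    """

    flair: np.ndarray
    dwi: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    subject_id: str = ""

    def __post_init__(self):
        if self.flair.shape != self.dwi.shape:
            raise AlignmentError(
                f"FLAIR shape {self.flair.shape} != DWI shape {self.dwi.shape}"
            )
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel geometry must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_thickness


@dataclass
class TissueMaps:
    """Per-voxel WM/GM/CSF probabilities aligned to the subject grid."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray

    def __post_init__(self):
        for name in ("wm", "gm", "csf"):
            a = getattr(self, name)
            if a.shape != self.wm.shape:
                raise AlignmentError("tissue maps must share one shape")
            if a.size and (a.min() < 0 or a.max() > 1):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")


def _fit_axis(n: int, target: int) -> tuple[slice, tuple[int, int]]:
    """Crop slice and pad widths taking one axis of length n to target."""
    if n >= target:
        start = (n - target) // 2
        return slice(start, start + target), (0, 0)
    before = (target - n) // 2
    return slice(0, n), (before, target - n - before)


def normalize_size(volume: np.ndarray, target_side: int = 256) -> np.ndarray:
    """Centre-crop or symmetrically zero-pad each slice to a square side.

    Works on any (..., rows, cols) array; values are never interpolated,
    so masks and probability maps keep their exact values.
    """
    volume = np.asarray(volume)
    rows, cols = volume.shape[-2:]
    rs, rpad = _fit_axis(rows, target_side)
    cs, cpad = _fit_axis(cols, target_side)
    out = volume[..., rs, cs]
    if rpad != (0, 0) or cpad != (0, 0):
        pad = [(0, 0)] * (volume.ndim - 2) + [rpad, cpad]
        out = np.pad(out, pad)
    return out


def select_slices(tissue: TissueMaps, presence_threshold: float = 0.5) -> list[int]:
    """Indices of slices where any WM, GM or CSF voxel exceeds the threshold."""
    present = np.stack([tissue.wm, tissue.gm, tissue.csf]).max(axis=0)
    keep = [i for i in range(present.shape[0]) if present[i].max() > presence_threshold]
    if not keep:
        raise NoBrainContentError("no slice contains brain tissue above threshold")
    return keep


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Whole-volume linear rescale to [0, 255].

    A constant volume carries no usable signal; it maps to all zeros
    with a warning rather than raising, so batch jobs survive corrupt
    subjects.
    """
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        logger.warning("constant-intensity volume (value %g); returning zeros", lo)
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo) * 255.0


def preprocess_subject(
    volumes: SubjectVolumes,
    tissue: TissueMaps,
    masks: dict[str, np.ndarray] | None = None,
    target_side: int = 256,
    presence_threshold: float = 0.5,
) -> tuple[SubjectVolumes, TissueMaps, dict[str, np.ndarray], list[int]]:
    """Full preprocessing chain applied in geometric lockstep.

    Size normalisation and slice selection are applied identically to
    FLAIR, DWI, tissue maps and every supplied mask; intensity
    normalisation is applied per modality volume.
    """
    masks = masks or {}
    for name, m in masks.items():
        if m.shape != volumes.flair.shape:
            raise AlignmentError(f"mask '{name}' not aligned to volumes")
    if tissue.wm.shape != volumes.flair.shape:
        raise AlignmentError("tissue maps not aligned to volumes")

    fl = normalize_size(volumes.flair, target_side)
    dw = normalize_size(volumes.dwi, target_side)
    tis = TissueMaps(*(normalize_size(getattr(tissue, k), target_side) for k in ("wm", "gm", "csf")))
    out_masks = {k: normalize_size(m, target_side) for k, m in masks.items()}

    keep = select_slices(tis, presence_threshold)
    fl, dw = fl[keep], dw[keep]
    tis = TissueMaps(tis.wm[keep], tis.gm[keep], tis.csf[keep])
    out_masks = {k: m[keep] for k, m in out_masks.items()}

    out_vol = replace(volumes, flair=normalize_intensity(fl), dwi=normalize_intensity(dw))
    return out_vol, tis, out_masks, keep
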