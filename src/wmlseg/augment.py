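"""Per-slice random affine augmentation applied jointly to images and masks.

Five transforms are drawn independently for every slice in every
training epoch: rotation in [-30, 30] degrees, shift in [-0.1, 0.1] of
the image side per axis, isotropic scaling in [0.95, 1.05], shear in
[0, 0.1] and a horizontal flip with probability 0.5. They are composed
into a single affine map about the slice centre and applied once, so the
image is resampled a single time (linear interpolation) and masks are
resampled with nearest-neighbour lookup, which keeps them strictly
binary. Augmentation is a training-time operation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AlignmentError

__all__ = ["TransformRanges", "TransformParams", "sample_transform", "apply_transform", "Augmenter"]

IDENTITY_RANGES = dict(rotation=(0, 0), shift=(0, 0), scale=(1, 1), shear=(0, 0), flip=False)


@dataclass(frozen=True)
class TransformRanges:
    """Sampling intervals; defaults are the study protocol."""

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    shift_fraction: tuple[float, float] = (-0.1, 0.1)
    scale: tuple[float, float] = (0.95, 1.05)
    shear: tuple[float, float] = (0.0, 0.1)
    flip_prob: float = 0.5


@dataclass(frozen=True)
class TransformParams:
    rotation_deg: float = 0.0
    shift_fraction: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    shear: float = 0.0
    flip: bool = False

    @classmethod
    def identity(cls) -> "TransformParams":
        return cls()


def sample_transform(rng: np.random.Generator, ranges: TransformRanges = TransformRanges()) -> TransformParams:
    """Draw one parameter set, every field uniform over its interval."""
    return TransformParams(
        rotation_deg=float(rng.uniform(*ranges.rotation_deg)),
        shift_fraction=(
            float(rng.uniform(*ranges.shift_fraction)),
            float(rng.uniform(*ranges.shift_fraction)),
        ),
        scale=float(rng.uniform(*ranges.scale)),
        shear=float(rng.uniform(*ranges.shear)),
        flip=bool(rng.random() < ranges.flip_prob),
    )


def _linear_part(params: TransformParams) -> np.ndarray:
    """2x2 forward map (row, col), composed flip . rotation . shear . scale."""
    th = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, params.shear], [0.0, 1.0]])
    scale = params.scale * np.eye(2)
    flip = np.diag([1.0, -1.0]) if params.flip else np.eye(2)
    return flip @ rot @ shear @ scale


def _is_identity(params: TransformParams) -> bool:
    return (
        params.rotation_deg == 0.0
        and params.shift_fraction == (0.0, 0.0)
        and params.scale == 1.0
        and params.shear == 0.0
        and not params.flip
    )


def apply_transform(
    image: np.ndarray,
    masks: list[np.ndarray] | tuple[np.ndarray, ...],
    params: TransformParams,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Apply one composed affine to a slice and its aligned masks.

    image may be (H, W) or (C, H, W); each mask is (H, W) and binary.
    The identical geometric map is used for image channels (linear
    interpolation, zero fill) and masks (nearest-neighbour, zero fill).
    """
    image = np.asarray(image)
    single = image.ndim == 2
    channels = image[None] if single else image
    shape = channels.shape[1:]
    for m in masks:
        if np.shape(m) != shape:
            raise AlignmentError(f"mask shape {np.shape(m)} != image shape {shape}")

    if _is_identity(params):
        out_img = image.copy()
        return (out_img, [np.asarray(m).copy() for m in masks])

    lin = _linear_part(params)
    centre = (np.array(shape) - 1) / 2.0
    shift_px = np.array(params.shift_fraction) * np.array(shape)
    # output -> input map for ndimage: p_in = L^-1 (p_out - centre - shift) + centre
    inv = np.linalg.inv(lin)
    offset = centre - inv @ (centre + shift_px)

    out_ch = [
        ndimage.affine_transform(c, inv, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False)
        for c in channels
    ]
    out_img = out_ch[0] if single else np.stack(out_ch)
    out_masks = []
    for m in masks:
        t = ndimage.affine_transform(
            np.asarray(m, dtype=np.float32), inv, offset=offset, order=0, mode="constant", cval=0.0
        )
        out_masks.append((t > 0.5).astype(np.asarray(m).dtype))
    return out_img, out_masks


class Augmenter:
    """Stateful per-slice augmenter for the training loop.

    Called as ``augmenter(image, mask)``; draws fresh parameters from
    its own seeded stream on every call.
    """

    def __init__(self, seed: int = 0, ranges: TransformRanges = TransformRanges()):
        self.ranges = ranges
        self.seed = seed
        self._rng = np.random.default_rng(seed)

    def __call__(self, image: np.ndarray, mask: np.ndarray):
        params = sample_transform(self._rng, self.ranges)
        img, (m,) = apply_transform(image, [mask], params)
        return img, m
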