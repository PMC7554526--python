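"""NIfTI and manifest I/O.

Arrays are handled internally as (slices, rows, cols); on disk the two
in-plane axes come first, so volumes round-trip through nibabel with
the voxel geometry encoded in the affine diagonal.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume"]


def save_volume(
    array: np.ndarray,
    path: str | Path,
    pixel_spacing: tuple[float, float],
    slice_thickness: float,
) -> None:
    """Write a (slices, rows, cols) array as NIfTI."""
    data = np.transpose(np.asarray(array), (1, 2, 0))
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], slice_thickness, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read a NIfTI volume back to (slices, rows, cols) plus geometry."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    return np.transpose(data, (2, 0, 1)), (float(zooms[0]), float(zooms[1])), float(zooms[2])
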