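"""NIfTI I/O and the in-memory subject-stack container."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeStack", "read_stack", "write_map", "read_mask"]

_AFFINE_TOL = 1e-4


@dataclass(frozen=True)
class VolumeStack:
    """n per-subject scalar volumes on one grid, with an analysis mask.

    ``data`` has shape ``(n, X, Y, Z)``; ``mask`` is boolean over the grid.
    Spatial metadata (the affine) is carried through untouched.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] < 2:
            raise ValueError(
                "data must be (n, X, Y, Z) with n >= 2 subject volumes, got "
                f"shape {self.data.shape}"
            )
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape does not match the volume grid")
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]


def _default_mask(data: np.ndarray) -> np.ndarray:
    """All-finite, non-constant voxels: the ones a t-test can use."""
    finite = np.isfinite(data).all(axis=0)
    varying = np.zeros_like(finite)
    varying[finite] = data[:, finite].std(axis=0) > 0
    return finite & varying


def read_stack(paths, mask_path=None) -> VolumeStack:
    """Load a subject stack from one 4-D NIfTI or a list of 3-D NIfTIs.

    All volumes must share grid shape, and affines must agree to within
    1e-4 elementwise.  Without an explicit mask, voxels that are finite in
    every subject and vary across subjects are analyzed.
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"{paths}: expected a 4-D volume, got shape {arr.shape}")
        data = np.moveaxis(arr, -1, 0)
        affine = img.affine
    else:
        paths = list(paths)
        if len(paths) < 2:
            raise ValueError("need at least 2 subject volumes")
        vols, affine = [], None
        for p in paths:
            img = nib.load(str(p))
            arr = np.asarray(img.dataobj, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3-D volume, got shape {arr.shape}")
            if affine is None:
                affine = img.affine
                shape = arr.shape
            else:
                if arr.shape != shape:
                    raise ValueError(
                        f"{p}: grid shape {arr.shape} does not match {shape}"
                    )
                if np.max(np.abs(img.affine - affine)) > _AFFINE_TOL:
                    raise ValueError(f"{p}: affine differs beyond {_AFFINE_TOL}")
            vols.append(arr)
        data = np.stack(vols, axis=0)
    if mask_path is not None:
        mask = read_mask(mask_path, expect_shape=data.shape[1:])
    else:
        mask = _default_mask(data)
    return VolumeStack(data=data, mask=mask, affine=affine)


def read_mask(path, expect_shape=None) -> np.ndarray:
    """Load a binary mask volume; any nonzero voxel is in-mask."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {arr.shape}")
    if expect_shape is not None and arr.shape != tuple(expect_shape):
        raise ValueError(
            f"{path}: mask shape {arr.shape} does not match grid {expect_shape}"
        )
    return arr != 0


def write_map(volume, affine, path) -> Path:
    """Write a scalar or binary volume as NIfTI-1, preserving the affine.

    Boolean / uint8 volumes are written as uint8 {0, 1}; everything else as
    float64 (NaN marks out-of-mask voxels).
    """
    path = Path(path)
    vol = np.asarray(volume)
    if vol.dtype == bool or vol.dtype == np.uint8:
        img = nib.Nifti1Image(vol.astype(np.uint8), np.asarray(affine))
    else:
        img = nib.Nifti1Image(vol.astype(np.float64), np.asarray(affine))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
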