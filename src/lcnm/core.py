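"""Shared containers for image volumes and region-of-interest sets.

Conventions used throughout the package:

* volumes are 3-D arrays indexed ``[i, j, k]`` with the *last* axis axial
  (slice index increases toward the superior/rostral end);
* masks are boolean arrays on the same grid as the volume they annotate;
* world coordinates (mm) follow the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

AXIAL_AXIS = 2


class GridError(ValueError):
    """Raised when volumes or masks do not share a common grid."""


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with voxel spacing metadata.

    Parameters
    ----------
    data:
        3-D float array of intensities (arbitrary units).
    voxel_size_mm:
        Per-axis voxel spacing in millimetres.
    affine:
        Optional 4x4 voxel-to-world matrix.  Defaults to a diagonal
        scaling by ``voxel_size_mm``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GridError(f"expected a 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be three positive spacings, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([*vs, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Copy of this volume carrying new intensity data on the same grid."""
        if np.shape(data) != self.data.shape:
            raise GridError("replacement data must match the volume grid")
        return replace(self, data=np.asarray(data, dtype=float))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to world coordinates in mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, voxel_size_mm=zooms, affine=np.asarray(img.affine))


def save_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    mask = np.asarray(mask)
    img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0


@dataclass
class ROISet:
    """Named binary masks on a common grid.

    ``search_roi_left`` / ``search_roi_right`` delimit where the locus
    coeruleus hyperintensity is sought; ``background_roi`` sits in central
    pons tissue free of hyperintense structures; ``brain_mask`` drives the
    slice-to-slice intensity normalization; ``reference_mask`` is the PET
    reference region and ``analysis_mask`` the voxel-wise analysis domain
    (both optional for MRI-only work).
    """

    search_roi_left: np.ndarray
    search_roi_right: np.ndarray
    background_roi: np.ndarray
    brain_mask: np.ndarray
    reference_mask: np.ndarray | None = None
    analysis_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in self._mask_names():
            m = getattr(self, name)
            if m is not None:
                setattr(self, name, np.asarray(m).astype(bool))

    @staticmethod
    def _mask_names() -> tuple[str, ...]:
        return (
            "search_roi_left",
            "search_roi_right",
            "background_roi",
            "brain_mask",
            "reference_mask",
            "analysis_mask",
        )

    def masks(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self._mask_names() if getattr(self, n) is not None}

    def validate(self, grid_shape: tuple[int, int, int]) -> list[str]:
        """Return a list of constraint violations (empty when valid)."""
        problems: list[str] = []
        for name, m in self.masks().items():
            if m.shape != tuple(grid_shape):
                problems.append(f"mask '{name}' has shape {m.shape}, expected {tuple(grid_shape)}")
        if not self.background_roi.any():
            problems.append("background_roi is empty")
        for side in ("left", "right"):
            roi = getattr(self, f"search_roi_{side}")
            if roi.shape == tuple(grid_shape):
                n_slices = len(np.unique(np.nonzero(roi)[AXIAL_AXIS]))
                if n_slices < 3:
                    problems.append(f"search_roi_{side} spans {n_slices} axial slices (< 3)")
                if (roi & self.background_roi).any():
                    problems.append(f"search_roi_{side} overlaps background_roi")
        return problems
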