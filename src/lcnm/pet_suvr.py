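"""FDG-PET standardized uptake value ratio (SUVR) computation and smoothing.

SUVR images are formed by dividing voxel-wise uptake by the *median* uptake
in a reference region (occipital in the study design, arbitrary mask here),
then smoothed with a Gaussian kernel specified by its full width at half
maximum (FWHM).  Partial-volume-effect correction is intentionally not
implemented: statistics run on non-PVE-corrected images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GridError, ImageVolume

#: FWHM = sigma * sqrt(8 ln 2)
FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class SUVRVolume:
    """A dimensionless uptake-ratio volume.

    ``reference_median`` is the divisor that was applied; ``fwhm_mm`` records
    smoothing already applied to ``volume`` (0 if none).  Before smoothing,
    the median of the values inside the reference mask is exactly 1.
    """

    volume: ImageVolume
    reference_median: float
    fwhm_mm: float = 0.0

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def compute_suvr(pet: ImageVolume, reference_mask: np.ndarray) -> SUVRVolume:
    """Divide uptake voxel-wise by the median uptake in the reference mask."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != pet.shape:
        raise GridError("reference mask grid does not match PET volume")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_median = float(np.median(pet.data[reference_mask]))
    if ref_median <= 0:
        raise ValueError(f"reference-region median uptake must be positive, got {ref_median}")
    return SUVRVolume(volume=pet.with_data(pet.data / ref_median), reference_median=ref_median)


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: tuple[float, float, float]) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxels for a given FWHM in mm."""
    return tuple(fwhm_mm / FWHM_PER_SIGMA / v for v in voxel_size_mm)


def smooth_gaussian(volume: ImageVolume, fwhm_mm: float, mode: str = "reflect") -> ImageVolume:
    """Separable Gaussian smoothing with anisotropic voxels handled per axis.

    ``fwhm_mm = 0`` is the identity.  The default reflective boundary keeps
    the total image sum preserved up to boundary handling.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.with_data(volume.data.copy())
    sigma = fwhm_to_sigma_vox(fwhm_mm, volume.voxel_size_mm)
    return volume.with_data(ndimage.gaussian_filter(volume.data, sigma=sigma, mode=mode))


def smooth_suvr(suvr: SUVRVolume, fwhm_mm: float) -> SUVRVolume:
    """Smoothed copy of an SUVR volume with the applied FWHM recorded."""
    sm = smooth_gaussian(suvr.volume, fwhm_mm)
    return SUVRVolume(volume=sm, reference_median=suvr.reference_median,
                      fwhm_mm=suvr.fwhm_mm + fwhm_mm if suvr.fwhm_mm else fwhm_mm)
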