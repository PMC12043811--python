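"""Biparametric MRI preprocessing: grid resampling and intensity normalization.

The three bpMRI sequences (T2W, DWI, ADC) arrive on different grids; the DWI
and ADC volumes are resampled to the space and size of the T2W volume so the
three can be stacked as channels of a single volume. T2W and DWI intensities
are Z-scored; ADC intensities are first clipped to the 0.5/99.5 percentiles
and then Z-scored using the clipped volume's statistics.

Axis convention: arrays are indexed (x, y, z), 0-based, matching the NIfTI
affine orientation used throughout the package. Physical position of voxel
``i`` along an axis is ``origin + i * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateVolumeError, GridMismatchError

__all__ = [
    "ImageVolume",
    "BpmriStack",
    "resample_to_reference",
    "zscore_normalize",
    "adc_normalize",
    "build_stack",
]


@dataclass
class ImageVolume:
    """A 3D scalar lattice with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities (or probabilities, or labels).
    spacing : tuple of float
        Voxel size in mm along each axis; strictly positive.
    origin : tuple of float
        Physical offset (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """New volume with the same geometry and different voxel values."""
        return replace(self, values=values)


@dataclass
class BpmriStack:
    """T2W/DWI/ADC volumes on one common grid, channel order fixed."""

    t2w: ImageVolume
    dwi: ImageVolume
    adc: ImageVolume

    def __post_init__(self) -> None:
        if not (self.t2w.same_grid(self.dwi) and self.t2w.same_grid(self.adc)):
            raise GridMismatchError("stack channels must share one grid")

    def as_array(self) -> np.ndarray:
        """(3, nx, ny, nz) channel-first array in (t2w, dwi, adc) order."""
        return np.stack([self.t2w.values, self.dwi.values, self.adc.values])


def resample_to_reference(
    moving: ImageVolume, reference: ImageVolume, mode: str = "linear"
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``reference``.

    ``mode='linear'`` trilinearly interpolates intensities; ``mode='nearest'``
    picks the nearest input voxel, preserving the input's value set (use for
    masks and label maps). Samples outside the moving volume clamp to its edge.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if any(n == 0 for n in reference.shape):
        raise ValueError("reference grid has zero size")
    if moving.same_grid(reference):
        return ImageVolume(moving.values.copy(), reference.spacing, reference.origin)

    idx = np.indices(reference.shape, dtype=float)
    coords = np.empty_like(idx)
    for ax in range(3):
        phys = reference.origin[ax] + idx[ax] * reference.spacing[ax]
        coords[ax] = (phys - moving.origin[ax]) / moving.spacing[ax]
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        moving.values.astype(float, copy=False), coords, order=order, mode="nearest"
    )
    if mode == "nearest":
        out = out.astype(moving.values.dtype)
    return ImageVolume(out, reference.spacing, reference.origin)


def _zscore_array(values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    sel = values if mask is None else values[mask]
    if sel.size == 0:
        raise DegenerateVolumeError("no voxels selected for normalization")
    mean = float(np.mean(sel))
    sd = float(np.std(sel))
    if sd == 0.0:
        raise DegenerateVolumeError("cannot Z-score a constant volume (zero variance)")
    return (values - mean) / sd


def zscore_normalize(vol: ImageVolume, mask: np.ndarray | None = None) -> ImageVolume:
    """Z-score a volume: subtract the mean, divide by the (population) SD.

    Statistics are computed over all voxels by default; pass a boolean ``mask``
    to restrict them (e.g. to the gland). A constant volume raises
    :class:`DegenerateVolumeError`.
    """
    return vol.with_values(_zscore_array(vol.values.astype(float), mask))


def adc_normalize(vol: ImageVolume, mask: np.ndarray | None = None) -> ImageVolume:
    """Normalize an ADC volume: percentile clip, then Z-score.

    Intensities are clipped to the volume's own 0.5 and 99.5 percentiles
    (linear-interpolation quantiles), then the clipped volume is Z-scored
    using its post-clip mean and SD.
    """
    values = vol.values.astype(float)
    sel = values if mask is None else values[mask]
    lo, hi = np.percentile(sel, [0.5, 99.5])
    clipped = np.clip(values, lo, hi)
    return vol.with_values(_zscore_array(clipped, mask))


def build_stack(t2w: ImageVolume, dwi: ImageVolume, adc: ImageVolume) -> BpmriStack:
    """Assemble a normalized bpMRI stack on the T2W grid.

    DWI and ADC are linearly resampled to the T2W grid; T2W and DWI are
    Z-scored and ADC is percentile-clipped then Z-scored.
    """
    dwi_r = resample_to_reference(dwi, t2w, mode="linear")
    adc_r = resample_to_reference(adc, t2w, mode="linear")
    return BpmriStack(
        t2w=zscore_normalize(t2w),
        dwi=zscore_normalize(dwi_r),
        adc=adc_normalize(adc_r),
    )
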