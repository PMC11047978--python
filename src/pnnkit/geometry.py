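"""Acquisition geometry and calibrated image stacks.

Coordinates follow the microscopy convention used throughout the package:
voxel arrays are indexed ``(z, y, x)``; physical positions are expressed in
micrometres as ``(x, y, z)`` with the centre of voxel ``(iz, iy, ix)`` at
``(ix * lateral_spacing, iy * lateral_spacing, iz * axial_spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "ImageStack",
    "SIM_GEOMETRY",
    "CONFOCAL_GEOMETRY",
    "PUNCTA_GEOMETRY",
]


class ParameterError(ValueError):
    """Raised when a physical or algorithmic parameter is out of range."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical calibration of a fluorescence stack.

    Parameters
    ----------
    lateral_spacing : float
        Pixel size in x and y, µm/voxel.
    axial_spacing : float
        Optical-slice spacing in z, µm/voxel.
    n_slices : int
        Number of optical slices.
    psf_sigma_lateral, psf_sigma_axial : float
        Gaussian PSF standard deviations in µm. The axial sigma is at least
        the lateral one (diffraction-limited optics are always worse in z).
    intensity_max : int
        Full-scale intensity; 8-bit acquisition fixes this at 255.
    """

    lateral_spacing: float
    axial_spacing: float
    n_slices: int
    psf_sigma_lateral: float
    psf_sigma_axial: float
    intensity_max: int = 255

    def __post_init__(self) -> None:
        if self.lateral_spacing <= 0 or self.axial_spacing <= 0:
            raise ParameterError("voxel spacings must be positive")
        if self.psf_sigma_lateral <= 0 or self.psf_sigma_axial < self.psf_sigma_lateral:
            raise ParameterError(
                "PSF sigmas must be positive with psf_sigma_axial >= psf_sigma_lateral"
            )
        if self.n_slices < 1:
            raise ParameterError("n_slices must be >= 1")
        if self.intensity_max != 255:
            raise ParameterError("only 8-bit (0-255) intensity ranges are supported")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel spacing as a ``(z, y, x)`` tuple in µm."""
        return (self.axial_spacing, self.lateral_spacing, self.lateral_spacing)

    @property
    def axial_extent(self) -> float:
        """Physical z extent of the stack in µm."""
        return self.n_slices * self.axial_spacing

    def sigma_voxels(self) -> tuple[float, float, float]:
        """PSF sigma per array axis ``(z, y, x)`` in voxel units."""
        return (
            self.psf_sigma_axial / self.axial_spacing,
            self.psf_sigma_lateral / self.lateral_spacing,
            self.psf_sigma_lateral / self.lateral_spacing,
        )


#: SIM-like super-resolution geometry: ~150 nm lateral / 300 nm axial
#: resolution (sigma = FWHM / 2.355), 125 nm slices, 52 slices.
SIM_GEOMETRY = AcquisitionGeometry(
    lateral_spacing=0.04,
    axial_spacing=0.125,
    n_slices=52,
    psf_sigma_lateral=0.064,
    psf_sigma_axial=0.127,
)

#: Confocal geometry for PNN / PV overview imaging (40× objective).
CONFOCAL_GEOMETRY = AcquisitionGeometry(
    lateral_spacing=0.2,
    axial_spacing=1.0,
    n_slices=7,
    psf_sigma_lateral=0.15,
    psf_sigma_axial=0.6,
)

#: Confocal geometry for synaptic-puncta imaging (63×/NA 1.4 oil, zoomed):
#: sub-µm boutons need ~0.1 µm sampling to be countable as particles.
PUNCTA_GEOMETRY = AcquisitionGeometry(
    lateral_spacing=0.1,
    axial_spacing=1.0,
    n_slices=7,
    psf_sigma_lateral=0.1,
    psf_sigma_axial=0.5,
)


@dataclass
class ImageStack:
    """A single-channel calibrated voxel array.

    ``data`` is ``(z, y, x)`` (a 2D image is stored as a single-slice
    stack); values live in the 0-255 range of 8-bit acquisition but the
    dtype may be uint8 or float depending on the processing stage.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel: str = "WFA"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ParameterError(f"stack must be 2D or 3D, got ndim={arr.ndim}")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_bounds(self) -> tuple[float, float, float]:
        """Upper physical corner ``(x, y, z)`` in µm (lower corner is 0)."""
        nz, ny, nx = self.data.shape
        g = self.geometry
        return (
            (nx - 1) * g.lateral_spacing,
            (ny - 1) * g.lateral_spacing,
            (nz - 1) * g.axial_spacing,
        )

    def max_projection(self) -> np.ndarray:
        """Maximum-intensity projection along z, shape ``(y, x)``."""
        return self.data.max(axis=0)
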