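"""Reading and writing calibrated TIFF stacks.

Stacks are written as ImageJ-style multi-page TIFFs (axis order Z,Y,X)
with the voxel calibration embedded: lateral spacing in the resolution
tags, axial spacing in the ImageJ ``spacing`` field.  Reading restores
both; a file without calibration is an error unless the caller supplies a
geometry, because every downstream measurement is in physical units.
"""

from __future__ import annotations

from pathlib import Path as FsPath

import numpy as np
import tifffile

from .geometry import SIM_GEOMETRY, AcquisitionGeometry, ImageStack

__all__ = ["read_stack", "write_stack", "StackIOError"]


class StackIOError(ValueError):
    """Raised when a stack file is unreadable or uncalibrated."""


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a calibrated multi-page TIFF."""
    g = stack.geometry
    data = np.asarray(stack.data)
    tifffile.imwrite(
        FsPath(path),
        data,
        imagej=True,
        resolution=(1.0 / g.lateral_spacing, 1.0 / g.lateral_spacing),
        metadata={
            "spacing": g.axial_spacing,
            "unit": "um",
            "axes": "ZYX",
            "pnnkit_psf_lateral": g.psf_sigma_lateral,
            "pnnkit_psf_axial": g.psf_sigma_axial,
            "pnnkit_channel": stack.channel,
        },
    )


def read_stack(
    path,
    geometry: AcquisitionGeometry | None = None,
    rescale_to_8bit: bool = False,
) -> ImageStack:
    """Read a calibrated TIFF stack.

    Calibration is taken from the file's resolution tags and ImageJ
    metadata; pass ``geometry`` to override or to supply calibration for
    plain TIFFs that carry none.  16-bit data is preserved unless
    ``rescale_to_8bit`` is set, in which case it is linearly mapped onto
    0-255.
    """
    p = FsPath(path)
    if not p.exists():
        raise StackIOError(f"stack file not found: {p}")
    try:
        with tifffile.TiffFile(p) as tf:
            data = tf.asarray()
            page = tf.pages[0]
            ij = tf.imagej_metadata or {}
            xres = page.tags.get("XResolution")
            channel = str(ij.get("pnnkit_channel", "WFA"))
            if geometry is None:
                if xres is None or "spacing" not in ij:
                    raise StackIOError(
                        f"{p} carries no voxel calibration; supply an "
                        "AcquisitionGeometry (or set geometry in the config)")
                num, den = xres.value
                lateral = den / num
                axial = float(ij["spacing"])
                nz = data.shape[0] if data.ndim == 3 else 1
                geometry = AcquisitionGeometry(
                    lateral_spacing=lateral,
                    axial_spacing=axial,
                    n_slices=nz,
                    psf_sigma_lateral=float(
                        ij.get("pnnkit_psf_lateral",
                               SIM_GEOMETRY.psf_sigma_lateral / SIM_GEOMETRY
                               .lateral_spacing * lateral)),
                    psf_sigma_axial=float(
                        ij.get("pnnkit_psf_axial",
                               max(axial, lateral * 2))),
                )
    except StackIOError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt files
        raise StackIOError(f"could not read TIFF stack {p}: {exc}") from exc

    if rescale_to_8bit and data.dtype != np.uint8:
        lo, hi = float(data.min()), float(data.max())
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        data = np.clip((data.astype(np.float64) - lo) * scale, 0,
                       255).astype(np.uint8)
    return ImageStack(data, geometry, channel=channel)
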