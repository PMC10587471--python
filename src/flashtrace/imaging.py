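"""Anisotropic 3D image stacks: container, preprocessing, and TIFF IO.

A confocal z-stack is an ordered series of 2D grayscale optical sections
with strongly anisotropic calibration (typically ~0.06 um/pixel in XY versus
~0.3 um between sections).  Sections are stored as a single (nz, ny, nx)
array; physical coordinates are ``x = column * xy_pixel``,
``y = row * xy_pixel``, ``z = section * z_step`` with pixel centers at
integer indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageStack",
    "max_intensity_projection",
    "preprocess",
    "read_stack",
    "write_stack",
]

SIDECAR_NAME = "calibration.yaml"


@dataclass
class ImageStack:
    """A z-stack of single-channel sections plus physical calibration."""

    sections: np.ndarray  # (nz, ny, nx)
    xy_pixel: float       # um / pixel
    z_step: float         # um / section

    def __post_init__(self) -> None:
        arr = np.asarray(self.sections)
        if arr.ndim != 3:
            raise ValueError(
                f"sections must be a (nz, ny, nx) array, got {arr.shape}")
        if self.xy_pixel <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        self.sections = arr

    @property
    def n_sections(self) -> int:
        return self.sections.shape[0]

    @property
    def shape(self) -> tuple:
        return self.sections.shape

    def to_physical(self, col: float, row: float, section: float) -> np.ndarray:
        """Pixel coordinates (x_px, y_px, section) -> (x, y, z) in um."""
        return np.array([col * self.xy_pixel, row * self.xy_pixel,
                         section * self.z_step])

    def to_pixel(self, x_um: float, y_um: float, z_um: float) -> np.ndarray:
        """Physical coordinates (um) -> continuous (x_px, y_px, section)."""
        return np.array([x_um / self.xy_pixel, y_um / self.xy_pixel,
                         z_um / self.z_step])


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Pixelwise maximum across sections (the standard 2D view of a stack)."""
    if stack.n_sections < 1:
        raise ValueError("empty stack")
    return stack.sections.max(axis=0)


def preprocess(stack: ImageStack) -> ImageStack:
    """Auto-contrast to [0, 1] globally and Gaussian-blur each section.

    The contrast stretch is global across the stack (per-section stretching
    would distort brightness comparisons between sections, which the tracer's
    across-section selection depends on).  The blur is 2D per section with a
    one-pixel radius; it suppresses single-pixel noise so that isolated hot
    pixels do not survive the tracer's peak-width filter.
    """
    arr = stack.sections.astype(np.float32, copy=True)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi - lo <= 0:
        raise ValueError("no contrast: stack has zero dynamic range")
    arr -= lo
    arr /= (hi - lo)
    for z in range(arr.shape[0]):
        gaussian_filter(arr[z], sigma=1.0, output=arr[z], mode="nearest")
    # blur can shrink the range slightly; restore the 0-1 contract
    lo2, hi2 = float(arr.min()), float(arr.max())
    if hi2 - lo2 <= 0:
        raise ValueError("no contrast: stack has zero dynamic range")
    arr -= lo2
    arr /= (hi2 - lo2)
    return replace(stack, sections=arr)


# ---------------------------------------------------------------------------
# disk format: one 16-bit grayscale TIFF per section + YAML sidecar
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, directory: str | Path,
                prefix: str = "section") -> Path:
    """Write a stack as 16-bit TIFF sections plus a calibration sidecar.

    Float data in [0, 1] is scaled to the full 16-bit range; integer data is
    written unchanged.  File names carry a zero-padded section index so that
    lexicographic order is acquisition order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = stack.sections
    if np.issubdtype(arr.dtype, np.floating):
        data = np.clip(arr, 0.0, 1.0)
        data = (data * 65535.0 + 0.5).astype(np.uint16)
    else:
        data = arr.astype(np.uint16)
    width = max(4, len(str(stack.n_sections - 1)))
    for z in range(stack.n_sections):
        tifffile.imwrite(directory / f"{prefix}_{z:0{width}d}.tif", data[z])
    sidecar = {"xy_pixel_um": float(stack.xy_pixel),
               "z_step_um": float(stack.z_step)}
    (directory / SIDECAR_NAME).write_text(yaml.safe_dump(sidecar))
    return directory


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack from a directory of TIFF sections or a multipage TIFF.

    Sections are ordered by filename (or page order); all sections must share
    one raster size and be single-channel.  Raw integer values are preserved
    -- normalization happens in :func:`preprocess`.  Calibration comes from a
    ``calibration.yaml`` sidecar ({xy_pixel_um, z_step_um}) in the directory
    (or next to the multipage file).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF sections in {path}")
        sections = [tifffile.imread(f) for f in files]
        names = [f.name for f in files]
        sidecar_path = path / SIDECAR_NAME
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sections = list(data)
        names = [f"page {i}" for i in range(len(sections))]
        sidecar_path = path.parent / SIDECAR_NAME

    bad = [n for n, s in zip(names, sections) if np.asarray(s).ndim != 2]
    if bad:
        raise ValueError(f"single-channel required; offending sections: {bad}")
    shapes = {np.asarray(s).shape for s in sections}
    if len(shapes) != 1:
        offenders = {n: np.asarray(s).shape for n, s in zip(names, sections)}
        raise ValueError(f"mixed section dimensions: {offenders}")

    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing calibration sidecar {sidecar_path} "
            "(expected keys xy_pixel_um, z_step_um)")
    cal = yaml.safe_load(sidecar_path.read_text())
    return ImageStack(np.stack(sections), xy_pixel=float(cal["xy_pixel_um"]),
                      z_step=float(cal["z_step_um"]))
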