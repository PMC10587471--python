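"""Render simulated fibers into synthetic confocal-like z-stacks.

The renderer stands in for image acquisition: it turns ground-truth fiber
polylines into anisotropic grayscale stacks with the statistical structure
the tracer assumes -- bright tubular paths on a noisy background, an
anisotropic point-spread blur, and optional transient signal gaps.  Because
the input polylines are known exactly, rendered stacks serve as
ground-truthed fixtures for evaluating tracing accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ImageStack
from .trajectory import FiberTrace

__all__ = ["RenderConfig", "render_stack", "densify_polyline"]

#: tube cross-section reaches half its peak at one fiber radius
_HALF_WIDTH_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


@dataclass
class RenderConfig:
    """Rendering parameters (all intensities as fractions of full scale)."""

    fiber_radius: float = 0.4       # um; used when a fiber has no radii
    peak_intensity: float = 0.8
    psf_sigma_xy: float = 0.05      # um
    psf_sigma_z: float = 0.15       # um
    background_level: float = 0.1
    noise_sd: float = 0.05
    gap_rate: float = 0.0           # expected gaps per 100 um of fiber
    gap_len_mean: float = 1.0       # um, exponential gap lengths
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fiber_radius", "peak_intensity", "psf_sigma_xy",
                     "psf_sigma_z", "background_level", "noise_sd",
                     "gap_rate", "gap_len_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.peak_intensity <= self.background_level:
            raise ValueError("peak_intensity must exceed background_level")


def densify_polyline(pts: np.ndarray, spacing: float
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a polyline at roughly uniform arc spacing.

    Returns (samples, arclengths, fractional point index) so that per-point
    attributes (e.g. radii) can be linearly interpolated onto the samples.
    Vertices are always included.
    """
    pts = np.asarray(pts, float)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    samples = [pts[0]]
    arcs = [0.0]
    fidx = [0.0]
    s0 = 0.0
    for i, ln in enumerate(seglen):
        n = max(1, int(np.ceil(ln / spacing)))
        t = np.arange(1, n + 1) / n
        seg = pts[i][None, :] + t[:, None] * (pts[i + 1] - pts[i])[None, :]
        samples.append(seg)
        arcs.append(s0 + t * ln)
        fidx.append(i + t)
        s0 += ln
    return (np.vstack([samples[0][None, :]] + samples[1:]),
            np.concatenate([[0.0]] + arcs[1:]),
            np.concatenate([[0.0]] + fidx[1:]))


def _draw_gaps(total_len: float, cfg: RenderConfig,
               rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Poisson-process gap starts along arc length, exponential lengths."""
    rate = cfg.gap_rate / 100.0  # per um
    if rate <= 0 or total_len <= 0:
        return []
    n = rng.poisson(rate * total_len)
    starts = np.sort(rng.uniform(0.0, total_len, n))
    lengths = rng.exponential(cfg.gap_len_mean, n)
    return [(float(s), float(s + l)) for s, l in zip(starts, lengths)]


def _in_gaps(arcs: np.ndarray, gaps: Sequence[Tuple[float, float]]
             ) -> np.ndarray:
    mask = np.zeros(arcs.shape, dtype=bool)
    for a, b in gaps:
        mask |= (arcs >= a) & (arcs <= b)
    return mask


def render_stack(fibers: Sequence,
                 volume: Tuple[float, float, float],
                 cal: Tuple[float, float],
                 cfg: RenderConfig,
                 forced_gaps: Optional[Sequence[Sequence[Tuple[float, float]]]]
                 = None) -> ImageStack:
    """Render fibers into a grayscale stack.

    Parameters
    ----------
    fibers : sequence
        Each element is a :class:`FiberTrace`, an (n, 3) point array, or a
        ``(points, radii)`` pair with per-point radii in um.  Points must lie
        inside the volume.
    volume : (Lx, Ly, Lz)
        Physical box size in um.
    cal : (xy_pixel, z_step)
        Voxel calibration in um.
    cfg : RenderConfig
    forced_gaps : optional
        Per-fiber list of explicit (start_um, end_um) arc-length intervals in
        which the signal is zeroed, in addition to the stochastic gaps drawn
        from ``cfg.gap_rate``.  Useful for controlled gap-crossing tests.

    The tube intensity profile is a Gaussian of the 3D distance to the
    polyline, scaled so it falls to half the peak at one fiber radius, and
    composited by maximum where fibers overlap.  An anisotropic Gaussian PSF
    blur is then applied, the background level added, and Gaussian noise
    (clamped to [0, 1]) superimposed.  Deterministic per ``cfg.seed``.
    """
    xy_pixel, z_step = cal
    if xy_pixel <= 0 or z_step <= 0:
        raise ValueError("calibration must be positive")
    Lx, Ly, Lz = volume
    nx = int(round(Lx / xy_pixel)) + 1
    ny = int(round(Ly / xy_pixel)) + 1
    nz = int(round(Lz / z_step)) + 1
    rng = np.random.default_rng(cfg.seed)

    tube = np.zeros((nz, ny, nx), dtype=np.float32)
    amplitude = cfg.peak_intensity - cfg.background_level

    for fi, fiber in enumerate(fibers):
        radii = None
        if isinstance(fiber, FiberTrace):
            pts = fiber.points
        elif isinstance(fiber, tuple):
            pts, radii = np.asarray(fiber[0], float), np.asarray(fiber[1], float)
        else:
            pts = np.asarray(fiber, float)
        if pts.shape[0] < 2:
            continue
        samples, arcs, fidx = densify_polyline(pts, spacing=xy_pixel)
        if radii is not None:
            i0 = np.floor(fidx).astype(int)
            i0 = np.minimum(i0, radii.size - 2)
            frac = fidx - i0
            r = radii[i0] * (1 - frac) + radii[i0 + 1] * frac
        else:
            r = np.full(samples.shape[0], cfg.fiber_radius)

        gaps = _draw_gaps(float(arcs[-1]), cfg, rng)
        if forced_gaps is not None and fi < len(forced_gaps):
            gaps = list(gaps) + list(forced_gaps[fi])
        keep = ~_in_gaps(arcs, gaps)

        _splat(tube, samples[keep], r[keep], amplitude, xy_pixel, z_step)

    if cfg.psf_sigma_xy > 0 or cfg.psf_sigma_z > 0:
        gaussian_filter(tube,
                        sigma=(cfg.psf_sigma_z / z_step,
                               cfg.psf_sigma_xy / xy_pixel,
                               cfg.psf_sigma_xy / xy_pixel),
                        output=tube, mode="nearest")

    tube += np.float32(cfg.background_level)
    if cfg.noise_sd > 0:
        for z in range(nz):  # per-section draws keep peak memory low
            tube[z] += rng.normal(0.0, cfg.noise_sd,
                                  size=(ny, nx)).astype(np.float32)
    np.clip(tube, 0.0, 1.0, out=tube)
    return ImageStack(tube, xy_pixel=xy_pixel, z_step=z_step)


def _splat(vol: np.ndarray, samples: np.ndarray, radii: np.ndarray,
           amplitude: float, xy_pixel: float, z_step: float) -> None:
    """Max-composite Gaussian blobs centered on polyline samples."""
    nz, ny, nx = vol.shape
    sigma = radii * _HALF_WIDTH_SIGMA  # um
    ext = 3.0 * sigma
    for (x, y, z), sg, e in zip(samples, sigma, ext):
        cx, cy, cz = x / xy_pixel, y / xy_pixel, z / z_step
        x0 = max(0, int(np.ceil(cx - e / xy_pixel)))
        x1 = min(nx - 1, int(np.floor(cx + e / xy_pixel)))
        y0 = max(0, int(np.ceil(cy - e / xy_pixel)))
        y1 = min(ny - 1, int(np.floor(cy + e / xy_pixel)))
        z0 = max(0, int(np.ceil(cz - e / z_step)))
        z1 = min(nz - 1, int(np.floor(cz + e / z_step)))
        if x1 < x0 or y1 < y0 or z1 < z0:
            continue
        dx = (np.arange(x0, x1 + 1) - cx) * xy_pixel
        dy = (np.arange(y0, y1 + 1) - cy) * xy_pixel
        dz = (np.arange(z0, z1 + 1) - cz) * z_step
        d2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dx[None, None, :] ** 2)
        blob = (amplitude * np.exp(-d2 / (2.0 * sg * sg))).astype(np.float32)
        sub = vol[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
        np.maximum(sub, blob, out=sub)
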