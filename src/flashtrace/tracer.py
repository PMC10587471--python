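"""The "flashlight" single-fiber tracing algorithm.

Starting from a seed point on a fiber, the tracer repeatedly scans pixel
intensities along an arc of radius R centered on the current point, oriented
toward the expected direction (the XY vector between the two most recent
points) and spanning [-alpha, alpha] -- like a flashlight beam pointed along
the fiber.  The same arc is evaluated in N optical sections above and below
the current one.  Detection is anisotropic on purpose: *within* a section
the surviving peak closest to the current direction wins, but *across*
sections the brightest candidate wins, reflecting that a confocal stack is a
pile of 2D images rather than an isotropic 3D image.

When no acceptable peak is found, the search radius is extended through
multiples of 0.5 R while the search angle optionally narrows exponentially;
this lets the trace bridge transient signal gaps at a controlled risk of
jumping to a neighboring fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .imaging import ImageStack, preprocess
from .trajectory import FiberTrace, nudge_trace

__all__ = [
    "TracerParams",
    "PeakCandidate",
    "TraceResult",
    "initialize",
    "scan_arc",
    "best_in_section",
    "select_next",
    "extension_schedule",
    "trace_fiber",
    "nudge_trace",
]

#: hard safety cap on automatic steps when the caller sets no max_steps
_SAFETY_CAP = 50_000


@dataclass
class TracerParams:
    """Tracing parameters.

    Defaults sit inside the typical working ranges for high-resolution
    confocal stacks of serotonergic axons (~60 nm/pixel XY, ~300 nm between
    sections, fiber diameter on the order of 1 um):

    R
        search radius = tracing step, um (typical 0.75-1.5)
    alpha0
        one-sided search angle, radians (typical ~pi/2)
    n
        one-sided number of angle increments; the arc is sampled at 2n + 1
        points, and the arc increment R * alpha0 / n should stay below half
        the expected fiber width
    k
        angle attenuation per extension (0 disables narrowing; typical 0-0.1)
    i_max
        maximal number of radius extensions (0-4; 0 disables gap bridging)
    B_min, B_max
        brightness window for peak detection, fractions of full scale
    W_min, W_max
        acceptable peak width (spatial extent at B_min) in um; the lower
        bound rejects single-pixel noise, the upper bound rejects blobs and
        varicosity-like saturated regions too wide to be a fiber cross
        section
    N
        number of neighboring optical sections scanned on each side; if
        None, round(R / z_step) is used at trace time
    self_avoid
        candidates closer than ``self_avoid * R`` (3D, um) to any earlier
        trace point (the current and previous points excepted) are rejected.
        This enforces the physical assumption that a fiber cannot fold back
        180 degrees onto itself: without it, a sub-radius extension arc
        (0.5 R) lying entirely inside the bright tube can orbit a fiber
        end indefinitely, and a trace that reverses at an apparent hairpin
        can slide back down its own tube.  Set 0 to disable.
    z_refine
        when True, the z-coordinate of each accepted point is refined to
        sub-section precision by a parabolic fit of log-brightness across
        the adjacent optical sections at the chosen XY position.  Peak
        detection and selection still work on whole sections; refinement
        only affects the recorded coordinate.  Without it, the ~z-step/2
        quantization error is comparable to the genuine step-to-step
        direction changes of a stiff fiber and biases downstream
        concentration-parameter estimates (it masks real z-motion on nearly
        in-plane fibers and adds spurious turning on inclined ones).
    xy_refine
        when True, the XY position of each accepted point is re-centered on
        the local brightness centroid of its section (window ~0.25 um,
        weights above B_min, shift clamped to the window).  The arc only
        samples a circle of radius R around the previous point, so where a
        fiber runs steeply through the sections its in-section blob is
        clipped off-center by the arc; the centroid recovers the ridge.
    spherical_arcs
        when False (default) the same arc radius is used in every scanned
        section, so 3D steps exceed R by the section offset and vary from
        step to step.  When True, the arc radius in a section offset by dz
        is sqrt(R^2 - dz^2) -- the search set becomes a sphere of radius R
        sliced by the sections -- so every accepted 3D step has length R.
        A constant 3D step removes the need to re-mark the trace afterwards
        and keeps step-direction statistics unbiased.
    z_profile_sigma
        Gaussian width (um) of a fiber's axial intensity profile, e.g. from
        a bead calibration of the axial PSF combined with the fiber radius.
        When set, sub-section z localization uses the two-section
        log-intensity ratio ``z = midpoint + (sigma^2 / dz) * ln(I_up /
        I_down)``, which behaves uniformly at every fiber inclination;
        when None, a three-section parabolic fit is used, which degrades
        to whole-section precision wherever the chosen section is not a
        local maximum of the axial profile.
    """

    R: float = 0.75
    alpha0: float = np.pi / 2
    n: int = 50
    k: float = 0.05
    i_max: int = 4
    B_min: float = 0.25
    B_max: float = 1.0
    W_min: float = 0.1
    W_max: float = 3.0
    N: Optional[int] = None
    self_avoid: float = 0.75
    z_refine: bool = True
    xy_refine: bool = True
    spherical_arcs: bool = False
    z_profile_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.R <= 0 or self.alpha0 <= 0 or self.n < 1:
            raise ValueError("R, alpha0 must be positive and n >= 1")
        if self.k < 0 or self.i_max < 0:
            raise ValueError("k and i_max must be nonnegative")
        if not (0 <= self.B_min < self.B_max):
            raise ValueError("need 0 <= B_min < B_max")
        if not (0 <= self.W_min < self.W_max):
            raise ValueError("need 0 <= W_min < W_max")
        # arc increment should stay below half the narrowest fiber width
        # the peak filter is asked to keep (2 * W_min / 2 == W_min)
        if self.R * self.alpha0 / self.n >= self.W_min:
            warnings.warn(
                "arc increment R*alpha0/n is not below half the minimal "
                "fiber width; the arc may undersample narrow fibers",
                stacklevel=2)


@dataclass
class PeakCandidate:
    """A surviving brightness peak on one scanned arc."""

    section_offset: int      # sections relative to the current section
    angle: float             # radians relative to the current direction
    brightness: float
    width: float             # arc-length extent at B_min, um
    pos_px: Tuple[float, float]  # (x_px, y_px) of the brightest arc sample


@dataclass
class TraceResult:
    """A traced fiber plus the per-point decision log."""

    trace: FiberTrace
    log: List[dict]          # step, section, angle, brightness, extension_i, origin
    termination: str         # no_peaks | stack_edge | max_steps | manual_stop
    params: TracerParams = field(repr=False, default=None)


def _bilinear(section: np.ndarray, xs: np.ndarray, ys: np.ndarray
              ) -> np.ndarray:
    return map_coordinates(section, [np.atleast_1d(ys), np.atleast_1d(xs)],
                           order=1, mode="constant", cval=0.0)


def extension_schedule(i: int, params: TracerParams
                       ) -> Tuple[float, float]:
    """Search radius and angle for extension index i.

    ``R_i = 0.5 * i * R`` (so i = 1 probes *below* the native radius, i = 2
    is the native radius, i = 3 is 1.5 R, ...) and
    ``alpha_i = alpha0 * exp(-k (i - 2))``, capped at ``alpha0``: the angle
    narrows with increasing extensions and never widens (a widened arc at
    the sub-radius extension would admit backward turns sharper than the
    nominal search angle).  After a successful extended step, both revert
    to (R, alpha0).
    """
    if i < 1:
        raise ValueError("extension index starts at 1")
    alpha = params.alpha0 * np.exp(-params.k * max(0, i - 2))
    return 0.5 * i * params.R, alpha


def scan_arc(section: np.ndarray, center: Tuple[float, float],
             direction: Tuple[float, float], R_um: float, alpha: float,
             params: TracerParams, xy_pixel: float,
             section_offset: int = 0) -> List[PeakCandidate]:
    """Scan one arc in one section and return the surviving peaks.

    The arc of radius ``R_um`` is sampled at 2n + 1 continuous positions
    spanning [-alpha, alpha] about the current direction, with bilinear
    intensity interpolation; samples outside the raster are skipped.
    Contiguous runs of samples with intensity >= B_min form peaks; a peak is
    discarded if its maximum exceeds B_max (saturation/blob guard) or if its
    width -- the arc length of the run -- falls outside [W_min, W_max].
    Each surviving peak is summarized by its brightest sample.
    """
    cx, cy = center
    base = np.arctan2(direction[1], direction[0])
    offsets = np.linspace(-alpha, alpha, 2 * params.n + 1)
    angles = base + offsets
    R_px = R_um / xy_pixel
    xs = cx + R_px * np.cos(angles)
    ys = cy + R_px * np.sin(angles)
    ny, nx = section.shape
    valid = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
    vals = np.zeros_like(xs)
    if valid.any():
        vals[valid] = _bilinear(section, xs[valid], ys[valid])
    above = valid & (vals >= params.B_min)

    inc_um = R_um * alpha / params.n  # arc length per increment
    candidates: List[PeakCandidate] = []
    j = 0
    m = above.size
    while j < m:
        if not above[j]:
            j += 1
            continue
        j0 = j
        while j < m and above[j]:
            j += 1
        j1 = j - 1
        run = slice(j0, j1 + 1)
        peak_val = float(vals[run].max())
        width = (j1 - j0) * inc_um
        if peak_val > params.B_max or width < params.W_min \
                or width > params.W_max:
            continue
        jm = j0 + int(np.argmax(vals[run]))
        candidates.append(PeakCandidate(
            section_offset=section_offset,
            angle=float(offsets[jm]),
            brightness=float(vals[jm]),
            width=float(width),
            pos_px=(float(xs[jm]), float(ys[jm])),
        ))
    return candidates


def best_in_section(candidates: Sequence[PeakCandidate]
                    ) -> Optional[PeakCandidate]:
    """Within a section, prefer the peak closest to the current direction.

    Ties on |angle| go to the brighter peak.
    """
    if not candidates:
        return None
    return min(candidates, key=lambda c: (abs(c.angle), -c.brightness))


def select_next(per_section: Dict[int, PeakCandidate]
                ) -> Optional[PeakCandidate]:
    """Across sections, prefer the brightest candidate.

    Ties on brightness go to the smaller |section offset|, then the smaller
    |angle|.  Returns None when no section produced a candidate ("no peak",
    which triggers the extension schedule).
    """
    if not per_section:
        return None
    return min(per_section.values(),
               key=lambda c: (-c.brightness, abs(c.section_offset),
                              abs(c.angle)))


def initialize(stack: ImageStack, seed_point: Tuple[float, float, int],
               params: TracerParams
               ) -> Tuple[Tuple[float, float, int], Tuple[float, float]]:
    """Find the second trace point on the circle of radius R around the seed.

    The seed must itself sit on a fiber (brightness >= B_min after
    preprocessing).  The second point is the brightness argmax over the full
    circle of radius R in the seed's section, restricted to points with
    brightness >= B_min; the initial current direction is the unit XY vector
    from the seed to it.
    """
    x, y, z = seed_point
    z = int(z)
    if not (0 <= z < stack.n_sections):
        raise ValueError(f"seed section {z} outside stack")
    section = stack.sections[z]
    seed_val = float(_bilinear(section, np.array([x]), np.array([y]))[0])
    if seed_val < params.B_min:
        raise ValueError(
            f"seed not on a fiber (brightness {seed_val:.3f} < "
            f"B_min {params.B_min})")
    m = int(np.ceil(2 * np.pi / (params.alpha0 / params.n)))
    angles = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    R_px = params.R / stack.xy_pixel
    xs = x + R_px * np.cos(angles)
    ys = y + R_px * np.sin(angles)
    ny, nx = section.shape
    valid = (xs >= 0) & (xs <= nx - 1) & (ys >= 0) & (ys <= ny - 1)
    vals = np.full(m, -np.inf)
    if valid.any():
        vals[valid] = _bilinear(section, xs[valid], ys[valid])
    if vals.max() < params.B_min:
        raise ValueError("seed not on a fiber (no circle point >= B_min)")
    jm = int(np.argmax(vals))
    second = (float(xs[jm]), float(ys[jm]), z)
    d = np.array([second[0] - x, second[1] - y])
    d /= np.linalg.norm(d)
    return second, (float(d[0]), float(d[1]))


def _refine_radial(section: np.ndarray, pos_px: Tuple[float, float],
                   direction: Tuple[float, float],
                   window_px: float) -> Tuple[float, float]:
    """Re-center a point along the motion direction by a parabolic peak fit.

    Where a fiber runs steeply through the sections, its in-section blob is
    clipped off-center by the search arc in the *radial* direction; the
    brightness profile along the motion direction is then sharply peaked and
    a log-parabola vertex recovers the blob center.  Where the fiber runs
    within the section, that profile is flat (it looks along the ridge) and
    the fit is left unused, so the correction cannot slide points along the
    fiber or shorten corners.
    """
    x, y = pos_px
    dx, dy = direction
    offsets = np.linspace(-window_px, window_px, 11)
    xs = x + offsets * dx
    ys = y + offsets * dy
    ny, nx = section.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or \
            ys.max() > ny - 1:
        return float(x), float(y)
    vals = _bilinear(section, xs, ys)
    j = int(np.argmax(vals))
    if j == 0 or j == vals.size - 1 or vals.min() <= 0:
        return float(x), float(y)
    l0, l1, l2 = np.log(vals[j - 1]), np.log(vals[j]), np.log(vals[j + 1])
    denom = l0 - 2.0 * l1 + l2
    h = offsets[1] - offsets[0]
    # require clear curvature: a flat along-ridge profile stays untouched
    if denom >= -0.01:
        return float(x), float(y)
    t = offsets[j] + h * (l0 - l2) / (2.0 * denom)
    t = float(np.clip(t, -window_px, window_px))
    return float(x + t * dx), float(y + t * dy)


def _refine_xy(section: np.ndarray, pos_px: Tuple[float, float],
               direction: Tuple[float, float], b_min: float,
               window_px: float) -> Tuple[float, float]:
    """Re-center a point on the ridge, strictly perpendicular to the motion.

    A 1D brightness centroid is taken along the in-section normal to the
    current step direction, with weights above B_min and the shift clamped
    to the window.  Restricting the correction to the normal re-centers a
    point that landed on the flank of the fiber's in-section blob without
    sliding it along the fiber -- a 2D (or iterated) centroid would shorten
    corners and systematically straighten the recovered trajectory.
    """
    x, y = pos_px
    nxv, nyv = -direction[1], direction[0]
    offsets = np.linspace(-window_px, window_px, 11)
    xs = x + offsets * nxv
    ys = y + offsets * nyv
    ny, nx = section.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or \
            ys.max() > ny - 1:
        return float(x), float(y)
    vals = _bilinear(section, xs, ys)
    w = np.clip(vals - b_min, 0.0, None)
    total = w.sum()
    if total <= 0:
        return float(x), float(y)
    t = float((w * offsets).sum() / total)
    return float(x + t * nxv), float(y + t * nyv)


def _refine_z_ratio(stack: ImageStack, pos_px: Tuple[float, float],
                    zi: int, sigma_um: float) -> float:
    """Sub-section z from the log-ratio of the two brightest sections.

    For a Gaussian axial profile of width sigma, the intensity ratio of two
    sections a distance dz apart fixes the peak position:
    ``z* = midpoint + (sigma^2 / dz) * ln(I_up / I_down)``.  Unlike a
    three-point parabolic fit this needs no interior maximum, so it behaves
    identically on flat and steeply inclined fibers.  The offset is clamped
    to +-0.6 sections around the chosen section.
    """
    x = np.array([pos_px[0]])
    y = np.array([pos_px[1]])

    def val(z):
        return float(_bilinear(stack.sections[z], x, y)[0])

    lo = val(zi - 1) if zi - 1 >= 0 else 0.0
    hi = val(zi + 1) if zi + 1 < stack.n_sections else 0.0
    if lo <= 0.0 and hi <= 0.0:
        return float(zi)
    # pair the chosen section with its brighter neighbor
    zn = zi + 1 if hi >= lo else zi - 1
    i0, i1 = val(zi), max(hi, lo)
    if i0 <= 0 or i1 <= 0:
        return float(zi)
    dz_um = stack.z_step
    off_um = (sigma_um ** 2 / dz_um) * np.log(i1 / i0)
    # offset of the peak from the midpoint of the pair, toward zn
    mid = 0.5 * (zi + zn)
    zf = mid + np.sign(zn - zi) * off_um / dz_um
    return float(np.clip(zf, zi - 0.6, zi + 0.6))


def _refine_z(stack: ImageStack, pos_px: Tuple[float, float],
              zi: int) -> float:
    """Sub-section z by parabolic fit of log-brightness across sections.

    The axial profile of a blurred tube is near-Gaussian, so log-brightness
    across three adjacent sections is near-parabolic and its vertex locates
    the fiber center between sections.  Falls back to the whole-section
    coordinate at stack faces or when the center section is not a local
    maximum; the offset is clamped to half a section.
    """
    if zi <= 0 or zi >= stack.n_sections - 1:
        return float(zi)
    x = np.array([pos_px[0]])
    y = np.array([pos_px[1]])

    def val(z):
        return float(_bilinear(stack.sections[z], x, y)[0])

    lo, mid, hi = val(zi - 1), val(zi), val(zi + 1)
    if mid <= lo or mid <= hi:
        # The XY position was refined after section selection, and at the
        # refined position the brightest section can shift by one (typical
        # for steeply inclined fibers).  Re-center once and retry.
        zn = zi - 1 if lo >= hi else zi + 1
        if zn <= 0 or zn >= stack.n_sections - 1:
            return float(zi)
        zi = zn
        lo, mid, hi = val(zi - 1), val(zi), val(zi + 1)
        if mid <= lo or mid <= hi:
            return float(zi)
    if lo <= 0 or hi <= 0:
        return float(zi)
    l0, l1, l2 = np.log(lo), np.log(mid), np.log(hi)
    denom = l0 - 2.0 * l1 + l2
    if denom >= -1e-12:
        return float(zi)
    off = (l0 - l2) / (2.0 * denom)
    return float(zi) + float(np.clip(off, -0.5, 0.5))


def _near_edge(x: float, y: float, z: float, stack: ImageStack,
               reach_um: float) -> bool:
    ny, nx = stack.sections.shape[1:]
    xy = stack.xy_pixel
    if min(x, nx - 1 - x) * xy < reach_um or \
       min(y, ny - 1 - y) * xy < reach_um:
        return True
    return min(z, stack.n_sections - 1 - z) * stack.z_step < reach_um


def trace_fiber(stack: ImageStack, seed_point: Tuple[float, float, int],
                params: Optional[TracerParams] = None,
                max_steps: Optional[int] = None,
                overrides: Optional[Sequence[Tuple[float, float, float]]] = None,
                do_preprocess: bool = True,
                step_hook=None, failure_hook=None) -> TraceResult:
    """Trace one fiber through a stack from a seed point.

    Parameters
    ----------
    stack : ImageStack
        Raw stack; set ``do_preprocess=False`` if it is already
        auto-contrasted and blurred.
    seed_point : (x_px, y_px, section)
        Pixel coordinates of a point on the fiber.
    params : TracerParams
    max_steps : int, optional
        Stop after this many automatic steps (termination ``max_steps``).
    overrides : sequence of (x_um, y_um, z_um), optional
        Manual bridge points, consumed in order whenever automatic detection
        fails (including after all extensions); each is inserted verbatim,
        flagged ``manual``, and tracing resumes from it.
    step_hook : callable, optional
        ``step_hook(point_um, log_entry)`` is called before each automatic
        point is committed; it may return None (accept), a replacement
        (x_um, y_um, z_um) point (recorded as ``manual`` -- the programmatic
        analog of a human correcting a wrong decision and letting the tracer
        continue), or the string ``"stop"`` to end the trace with
        termination ``manual_stop``.
    failure_hook : callable, optional
        ``failure_hook(current_point_um)`` is consulted when automatic
        detection fails even after all extensions and the override queue is
        exhausted; it may return a manual bridge point (x_um, y_um, z_um)
        from which tracing resumes, or None to let the trace terminate.

    Iterates: scan the current section and N neighbors on each side with the
    native (R, alpha0) arc; on failure, walk the extension schedule
    i = 1 .. i_max + 2; append the selected candidate; update the current
    direction from the XY vector between the two most recent points.
    Terminates with ``no_peaks``, ``stack_edge`` (no peak while within reach
    of a stack border), or ``max_steps``.  Fully deterministic.
    """
    params = params or TracerParams()
    pp = preprocess(stack) if do_preprocess else stack
    # N ~ R / z-step; round up so the scanned slab always reaches the
    # tracing radius (a fiber can climb nearly one R per step)
    N = params.N if params.N is not None \
        else max(1, int(np.ceil(params.R / pp.z_step - 1e-9)))
    override_queue = list(overrides) if overrides else []
    for ox, oy, oz in override_queue:
        px = pp.to_pixel(ox, oy, oz)
        ny, nx = pp.sections.shape[1:]
        if not (0 <= px[0] <= nx - 1 and 0 <= px[1] <= ny - 1
                and 0 <= px[2] <= pp.n_sections - 1):
            raise ValueError(f"override point ({ox}, {oy}, {oz}) um "
                             "lies outside the stack")

    sx, sy, sz = float(seed_point[0]), float(seed_point[1]), int(seed_point[2])
    second, direction = initialize(pp, (sx, sy, sz), params)

    pts: List[Tuple[float, float, float]] = [
        (sx, sy, float(sz)), (second[0], second[1], float(second[2]))]
    seed_b = float(_bilinear(pp.sections[sz], np.array([sx]),
                             np.array([sy]))[0])
    sec_b = float(_bilinear(pp.sections[sz], np.array([second[0]]),
                            np.array([second[1]]))[0])
    log: List[dict] = [
        {"step": 0, "section": sz, "angle": 0.0, "brightness": seed_b,
         "extension_i": 0, "origin": "seed"},
        {"step": 1, "section": sz, "angle": 0.0, "brightness": sec_b,
         "extension_i": 2, "origin": "auto"},
    ]

    termination = "no_peaks"
    cap = max_steps if max_steps is not None else _SAFETY_CAP
    while True:
        if len(pts) - 2 >= cap:
            termination = "max_steps"
            break
        cx, cy, cz = pts[-1]
        czi = int(round(cz))
        px, py, _ = pts[-2]
        dx, dy = cx - px, cy - py
        nrm = float(np.hypot(dx, dy))
        if nrm > 1e-9:
            direction = (dx / nrm, dy / nrm)
        # else: pure-Z move, carry the previous direction over

        # self-overlap guard: candidates must keep clear of the trace's own
        # past; the last few points are exempt so that ordinary consecutive
        # geometry (and locally clustered corrections) is never penalized,
        # while folds onto older parts of the trace are
        guard = params.self_avoid * params.R
        if guard > 0 and len(pts) > 4:
            prior = np.array(
                [[x * pp.xy_pixel, y * pp.xy_pixel, z * pp.z_step]
                 for x, y, z in pts[:-4]])
        else:
            prior = None

        def _refine(cand: PeakCandidate, R_used: float
                    ) -> Tuple[Tuple[float, float], float]:
            """Sub-pixel refinement of an accepted candidate -> (pos, zf)."""
            zi = czi + cand.section_offset
            pos = cand.pos_px
            if params.xy_refine:
                sd = np.array([pos[0] - cx, pos[1] - cy])
                nrm2 = float(np.hypot(*sd))
                if nrm2 > 1e-9:
                    sd /= nrm2
                    d2 = (float(sd[0]), float(sd[1]))
                    win = 0.25 / pp.xy_pixel
                    pos = _refine_radial(pp.sections[zi], pos, d2, win)
                    pos = _refine_xy(pp.sections[zi], pos, d2,
                                     params.B_min, win)
            if not params.z_refine:
                zf = float(zi)
            elif params.z_profile_sigma is not None:
                zf = _refine_z_ratio(pp, pos, zi, params.z_profile_sigma)
            else:
                zf = _refine_z(pp, pos, zi)
            if params.spherical_arcs:
                # z refinement changes the 3D step length after the
                # candidate was placed on the R-sphere; slide the point
                # radially in XY so the step is exactly R again
                dz_um = (zf - cz) * pp.z_step
                rad2 = R_used ** 2 - dz_um ** 2
                if rad2 > (0.2 * params.R) ** 2:
                    need_px = np.sqrt(rad2) / pp.xy_pixel
                    vx, vy = pos[0] - cx, pos[1] - cy
                    nv = float(np.hypot(vx, vy))
                    max_slide_px = 0.30 / pp.xy_pixel
                    if nv > 1e-9 and abs(need_px - nv) <= max_slide_px:
                        pos = (cx + vx / nv * need_px,
                               cy + vy / nv * need_px)
            return (float(pos[0]), float(pos[1])), zf

        def _violates_guard(pos, zf) -> bool:
            if prior is None:
                return False
            cum = np.array([pos[0] * pp.xy_pixel, pos[1] * pp.xy_pixel,
                            zf * pp.z_step])
            return bool(np.min(np.linalg.norm(prior - cum, axis=1)) < guard)

        chosen = None
        chosen_pos = None
        chosen_zf = None
        used_i = 2
        max_reach = params.R
        for i in [2] + list(range(1, params.i_max + 3)):
            R_i, alpha_i = extension_schedule(i, params)
            max_reach = max(max_reach, R_i)
            per_section: Dict[int, PeakCandidate] = {}
            N_i = N
            if params.spherical_arcs:
                N_i = max(N, int(R_i / pp.z_step))
            for off in range(-N_i, N_i + 1):
                zi = czi + off
                if not (0 <= zi < pp.n_sections):
                    continue
                r_xy = R_i
                if params.spherical_arcs:
                    rsq = R_i ** 2 - (off * pp.z_step) ** 2
                    if rsq <= (0.25 * params.R) ** 2:
                        continue
                    r_xy = float(np.sqrt(rsq))
                cands = scan_arc(pp.sections[zi], (cx, cy), direction,
                                 r_xy, alpha_i, params, pp.xy_pixel,
                                 section_offset=off)
                if prior is not None and cands:
                    cands = [c for c in cands if not _violates_guard(
                        c.pos_px, float(zi))]
                best = best_in_section(cands)
                if best is not None:
                    per_section[off] = best
            # refine the winning candidate; if refinement collapses it back
            # onto the trace's own past, drop it and try the next section
            while per_section:
                cand = select_next(per_section)
                pos2, zf2 = _refine(cand, R_i)
                if _violates_guard(pos2, zf2):
                    per_section.pop(cand.section_offset)
                    continue
                chosen, chosen_pos, chosen_zf = cand, pos2, zf2
                break
            if chosen is not None:
                used_i = i
                break

        if chosen is None:
            bridge = None
            if override_queue:
                bridge = override_queue.pop(0)
            elif failure_hook is not None:
                cur_um = (cx * pp.xy_pixel, cy * pp.xy_pixel, cz * pp.z_step)
                bridge = failure_hook(cur_um)
            if bridge is not None:
                ox, oy, oz = bridge
                opx = pp.to_pixel(ox, oy, oz)
                zi = int(round(opx[2]))
                b = float(_bilinear(pp.sections[zi], np.array([opx[0]]),
                                    np.array([opx[1]]))[0])
                pts.append((float(opx[0]), float(opx[1]), float(opx[2])))
                log.append({"step": len(pts) - 1, "section": zi,
                            "angle": 0.0, "brightness": b,
                            "extension_i": 0, "origin": "manual"})
                continue
            if _near_edge(cx, cy, cz, pp, max_reach):
                termination = "stack_edge"
            break

        zi = czi + chosen.section_offset
        pos = chosen_pos
        zf = chosen_zf
        chosen.pos_px = pos
        entry = {"step": len(pts), "section": zi,
                 "angle": chosen.angle, "brightness": chosen.brightness,
                 "extension_i": used_i, "origin": "auto"}
        if step_hook is not None:
            point_um = np.array([chosen.pos_px[0] * pp.xy_pixel,
                                 chosen.pos_px[1] * pp.xy_pixel,
                                 zf * pp.z_step])
            verdict = step_hook(point_um, entry)
            if isinstance(verdict, str) and verdict == "stop":
                termination = "manual_stop"
                break
            if verdict is not None:
                vx = pp.to_pixel(*verdict)
                vzi = int(round(vx[2]))
                b = float(_bilinear(pp.sections[vzi], np.array([vx[0]]),
                                    np.array([vx[1]]))[0])
                pts.append((float(vx[0]), float(vx[1]), float(vx[2])))
                log.append({"step": len(pts) - 1, "section": vzi,
                            "angle": 0.0, "brightness": b,
                            "extension_i": used_i, "origin": "manual"})
                continue
        pts.append((chosen.pos_px[0], chosen.pos_px[1], zf))
        log.append(entry)

    coords = np.array([[x * pp.xy_pixel, y * pp.xy_pixel, z * pp.z_step]
                       for x, y, z in pts])
    # hooks can in principle re-commit the same location; keep the first
    dup = np.r_[False, np.all(np.isclose(np.diff(coords, axis=0), 0.0,
                                         atol=1e-12), axis=1)]
    if dup.any():
        coords = coords[~dup]
        log = [e for e, d in zip(log, dup) if not d]
    trace = FiberTrace(coords, step_len=None,
                       meta={"source": "traced", "seed_point": list(seed_point),
                             "termination": termination})
    return TraceResult(trace=trace, log=log, termination=termination,
                       params=params)
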