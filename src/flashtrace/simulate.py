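"""Step-wise von Mises-Fisher random-walk fibers and multi-fiber volumes.

A simulated fiber advances in constant-length steps whose directions follow
the vMF distribution with a fixed concentration parameter kappa and a mean
direction equal to the previous step.  Volumes emulate multicolor (Brainbow)
labeling: many fibers seeded uniformly in a box, clipped to the box, each
with a random color and per-point radii drawn from a normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .trajectory import FiberTrace
from .vmf import MU0, _check_unit, sample_vmf_rng

__all__ = [
    "WalkConfig",
    "VolumeConfig",
    "ClippedFiber",
    "simulate_fiber",
    "simulate_volume",
    "sample_radii",
]

#: fiber radii below this bound (um) are redrawn; a normal radius model has
#: negative mass that a physical fiber cannot realize
RADIUS_FLOOR_UM = 0.02


@dataclass
class WalkConfig:
    """Parameters of a single random-walk fiber."""

    kappa: float
    n_steps: int
    step_len: float  # um
    start: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    init_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_len <= 0:
            raise ValueError("step_len must be positive")
        _check_unit(np.asarray(self.init_direction, float), "init_direction")


@dataclass
class VolumeConfig:
    """Parameters of a multi-fiber volume simulation.

    Defaults match a typical multicolor imaging volume: a 185 x 185 x 21 um
    box, fibers of 300 steps of 1.5 um with kappa = 15, radii drawn from
    Normal(0.20 um, 0.15 um).
    """

    dims: Tuple[float, float, float] = (185.0, 185.0, 21.0)  # um
    n_fibers: int = 300
    kappa: float = 15.0
    n_steps: int = 300
    step_len: float = 1.5  # um
    radius_mean: float = 0.20  # um
    radius_sd: float = 0.15  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("volume dims must be positive")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        if self.kappa <= 0 or self.n_steps < 1 or self.step_len <= 0:
            raise ValueError("invalid walk parameters")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")


@dataclass
class ClippedFiber:
    """One volume fiber: full walk, in-box segments, radii and color."""

    trace: FiberTrace                      # the unclipped walk
    segments: List[np.ndarray]             # retained runs of in-box points
    radii: np.ndarray                      # per-point radii (um), full walk
    radii_segments: List[np.ndarray]       # radii matching each segment
    color: np.ndarray                      # RGB in [0, 1]
    n_retained: int
    n_discarded: int

    def segment_traces(self, min_points: int = 2) -> List[FiberTrace]:
        """Retained segments as FiberTrace objects (single points dropped)."""
        out = []
        for seg in self.segments:
            if seg.shape[0] >= max(2, min_points):
                out.append(FiberTrace(seg, step_len=self.trace.step_len,
                                      meta=dict(self.trace.meta)))
        return out


def _walk(kappa: float, n_steps: int, step_len: float, start: np.ndarray,
          init_direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((n_steps + 1, 3))
    pts[0] = start
    direction = init_direction
    for i in range(n_steps):
        direction = sample_vmf_rng(direction, kappa, 1, rng)[0]
        direction /= np.linalg.norm(direction)
        pts[i + 1] = pts[i] + step_len * direction
    return pts


def simulate_fiber(cfg: WalkConfig) -> FiberTrace:
    """Simulate one fiber as a step-wise vMF random walk.

    The first step is taken along ``cfg.init_direction``; each subsequent
    step direction is a vMF draw whose mean is the previous step's direction.
    The result has ``n_steps + 1`` points with every consecutive distance
    equal to ``step_len`` (so a 300-step walk at 1.5 um has a path length of
    exactly 450 um).  Identical seeds give identical traces.
    """
    rng = np.random.default_rng(cfg.seed)
    pts = _walk(cfg.kappa, cfg.n_steps, cfg.step_len,
                np.asarray(cfg.start, float),
                np.asarray(cfg.init_direction, float), rng)
    meta = {"kappa": cfg.kappa, "seed": cfg.seed, "source": "simulated"}
    return FiberTrace(pts, step_len=cfg.step_len, meta=meta)


def sample_radii(n: int, mean: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-point fiber radii: Normal(mean, sd), redrawn below the floor."""
    r = rng.normal(mean, sd, n)
    bad = r < RADIUS_FLOOR_UM
    while np.any(bad):
        r[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = r < RADIUS_FLOOR_UM
    return r


def _clip_segments(pts: np.ndarray, dims: Tuple[float, float, float]
                   ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Split a walk into runs of points inside the closed box [0,L]^3."""
    inside = np.all((pts >= 0.0) & (pts <= np.asarray(dims)), axis=1)
    segments: List[np.ndarray] = []
    start = None
    for i, ok in enumerate(inside):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segments.append(pts[start:i].copy())
            start = None
    if start is not None:
        segments.append(pts[start:].copy())
    return segments, inside


def simulate_volume(cfg: VolumeConfig) -> List[ClippedFiber]:
    """Simulate a box full of fibers, clipped to the box.

    Fiber start points are uniform in the volume, initial directions uniform
    on the sphere.  Points falling outside the closed box are discarded (the
    walk itself passes through and may re-enter, yielding several disjoint
    retained segments per fiber); segments are not geometrically intersected
    with the boundary.  Radii are drawn per point from
    Normal(radius_mean, radius_sd) truncated at 0.02 um; each fiber gets a
    uniform random RGB color.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    dims = np.asarray(cfg.dims, float)
    fibers: List[ClippedFiber] = []
    for _ in range(cfg.n_fibers):
        start = rng.uniform(0.0, 1.0, 3) * dims
        init = rng.normal(size=3)
        init /= np.linalg.norm(init)
        pts = _walk(cfg.kappa, cfg.n_steps, cfg.step_len, start, init, rng)
        radii = sample_radii(pts.shape[0], cfg.radius_mean, cfg.radius_sd, rng)
        color = rng.uniform(0.0, 1.0, 3)
        segments, inside = _clip_segments(pts, cfg.dims)
        seg_radii = []
        # re-slice radii with the same run boundaries as the points
        idx = np.flatnonzero(inside)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                seg_radii.append(radii[run].copy())
        trace = FiberTrace(pts, step_len=cfg.step_len,
                           meta={"kappa": cfg.kappa, "source": "simulated"})
        fibers.append(ClippedFiber(
            trace=trace, segments=segments, radii=radii,
            radii_segments=seg_radii, color=color,
            n_retained=int(inside.sum()),
            n_discarded=int((~inside).sum()),
        ))
    return fibers
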