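"""Fiber trajectories as ordered 3D point sequences.

A :class:`FiberTrace` is the common currency of the package: the random-walk
simulator produces one, the image tracer reconstructs one from a z-stack, and
the directional-statistics layer consumes one.  Coordinates are physical
micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FiberTrace", "tortuosity", "nudge_trace"]

#: tolerance used to check the constant-step invariant, in micrometres
_STEP_TOL = 1e-6


@dataclass
class FiberTrace:
    """An ordered polyline of 3D points in micrometres.

    Parameters
    ----------
    points : ndarray, shape (n, 3)
        Ordered XYZ coordinates in micrometres; ``n >= 2`` and consecutive
        points must be distinct.
    step_len : float or None
        If a number, every consecutive Euclidean distance must equal it
        (within 1e-6 um).  ``None`` marks a variable-step trace, e.g. a raw
        tracer output before nudging.
    meta : dict
        Optional provenance (generating kappa, seed, source, ...).
    """

    points: np.ndarray
    step_len: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be an (n, 3) array, got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a fiber trace needs at least 2 points")
        d = self.step_lengths_of(pts)
        if np.any(d == 0.0):
            idx = int(np.argmin(d))
            raise ValueError(f"consecutive points {idx} and {idx + 1} coincide")
        if self.step_len is not None:
            if not np.allclose(d, self.step_len, rtol=0.0, atol=_STEP_TOL):
                worst = int(np.argmax(np.abs(d - self.step_len)))
                raise ValueError(
                    f"step {worst} has length {d[worst]:.6g} um, expected "
                    f"constant step {self.step_len:.6g} um"
                )
        self.points = pts

    @staticmethod
    def step_lengths_of(pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def step_lengths(self) -> np.ndarray:
        """Euclidean length of every segment, in micrometres."""
        return self.step_lengths_of(self.points)

    def path_length(self) -> float:
        """Total polyline length in micrometres."""
        return float(self.step_lengths().sum())

    def end_to_end(self) -> float:
        """Euclidean distance between the first and last point."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


def tortuosity(trace: FiberTrace) -> float:
    """Tortuosity index: path length over end-to-end distance.

    Equals 1 for a perfectly straight fiber and grows with meandering.  It is
    scale-invariant but, being a single ratio, varies strongly between
    realizations of the same stochastic process -- which is why the package
    prefers the concentration parameter as the primary stiffness summary.
    """
    d = trace.end_to_end()
    if d <= 1e-9:
        raise ValueError("undefined tortuosity (closed path)")
    return trace.path_length() / d


def nudge_trace(trace: FiberTrace, step_len: float) -> FiberTrace:
    """Resample a polyline to a constant 3D Euclidean step ("nudging").

    Slides along the original polyline, re-marking points so that consecutive
    output points are separated by exactly ``step_len`` in 3D.  Each output
    point is the first position along the remaining polyline whose *chord*
    distance from the previous output point equals ``step_len``; every output
    point therefore lies on the source polyline.  The first input point is
    preserved and a trailing remainder shorter than ``step_len`` is dropped.

    A constant step is a precondition for unbiased concentration-parameter
    estimation, because the von Mises-Fisher walk model assumes equal-length
    segments.
    """
    if step_len <= 0:
        raise ValueError("step_len must be positive")
    pts = trace.points
    if trace.path_length() < step_len:
        raise ValueError(
            f"step_len {step_len:.6g} um exceeds polyline length "
            f"{trace.path_length():.6g} um"
        )

    out = [pts[0].copy()]
    seg = 0  # index of the segment currently being walked
    t = 0.0  # fractional position within that segment
    nseg = pts.shape[0] - 1
    while True:
        p = out[-1]
        hit = None
        s, tt = seg, t
        while s < nseg:
            a, b = pts[s], pts[s + 1]
            ab = b - a
            # solve |a + u*ab - p|^2 = step_len^2 for u in (tt, 1]
            ap = a - p
            A = float(ab @ ab)
            B = 2.0 * float(ap @ ab)
            C = float(ap @ ap) - step_len * step_len
            disc = B * B - 4.0 * A * C
            if disc >= 0.0 and A > 0.0:
                sq = np.sqrt(disc)
                for u in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
                    if tt < u <= 1.0 + 1e-12:
                        # take the first forward crossing of the sphere
                        hit = (s, min(u, 1.0))
                        break
            if hit is not None:
                break
            s, tt = s + 1, 0.0
        if hit is None:
            break
        seg, t = hit
        out.append(pts[seg] + t * (pts[seg + 1] - pts[seg]))

    if len(out) < 2:
        # the whole polyline folds back inside the first sphere
        raise ValueError(
            f"no point on the polyline lies at chord distance "
            f"{step_len:.6g} um from the start; choose a smaller step")
    meta = dict(trace.meta)
    meta["nudged_from_step"] = trace.step_len
    return FiberTrace(np.asarray(out), step_len=step_len, meta=meta)
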