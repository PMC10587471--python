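"""Sampling-step calibration for concentration-parameter estimates.

A kappa estimate depends on the step at which a trajectory is sampled:
oversampling (steps much smaller than the fiber's natural step) makes the
fiber look artificially rigid and grossly inflates kappa, while undersampling
lowers it mildly and eventually destabilizes the estimate.  Plotting kappa
against the step multiplier on log-log axes produces a characteristic elbow
("inflection") at the natural step, which this module locates via the
discrete second difference of the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .trajectory import FiberTrace, nudge_trace
from .vmf import estimate_kappa, standardize_steps

__all__ = [
    "StepKappaCurve",
    "resample_trace",
    "kappa_step_curve",
    "find_inflection",
]

logger = logging.getLogger(__name__)

#: the canonical factor grid: fractions 1/10..1/2, 1, integers 2..10
DEFAULT_FACTORS = tuple(1.0 / m for m in range(10, 1, -1)) + tuple(
    float(f) for f in range(1, 11))

_FACTOR_TOL = 1e-9


@dataclass
class StepKappaCurve:
    """kappa estimates as a function of the step multiplier."""

    factors: np.ndarray          # strictly increasing positive multipliers
    kappa_per_fiber: np.ndarray  # (n_factors, n_fibers); NaN where skipped
    mode: str

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, float)
        if np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValueError("factors must be positive and strictly increasing")
        self.factors = f
        self.kappa_per_fiber = np.atleast_2d(
            np.asarray(self.kappa_per_fiber, float))

    @property
    def kappa_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.kappa_per_fiber, axis=1)

    @property
    def kappa_sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.kappa_per_fiber, axis=1, ddof=0)

    @property
    def n_fibers(self) -> np.ndarray:
        return np.sum(np.isfinite(self.kappa_per_fiber), axis=1)


def _fraction_denominator(factor: float) -> Optional[int]:
    inv = 1.0 / factor
    m = int(round(inv))
    if m >= 2 and abs(inv - m) < 1e-6:
        return m
    return None


def resample_trace(trace: FiberTrace, factor: float,
                   mode: str = "subdivide_subsample") -> FiberTrace:
    """Resample a trace at ``factor`` times its native step.

    ``subdivide_subsample`` (exact, for constant-step traces):
        a fractional factor 1/m inserts m - 1 equally spaced points on every
        segment; an integer factor f keeps every f-th point (the first point
        is always kept); factor 1 is the identity.
    ``renudge`` (for traced data whose native step is a tool artifact):
        slides along the polyline re-marking points at a constant 3D step of
        ``factor * native_step`` (see :func:`nudge_trace`).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    pts = trace.points

    if mode == "subdivide_subsample":
        if abs(factor - 1.0) < _FACTOR_TOL:
            return trace
        m = _fraction_denominator(factor)
        if m is not None:
            t = np.arange(1, m + 1) / m
            segs = pts[:-1, None, :] + t[None, :, None] * (
                np.diff(pts, axis=0)[:, None, :])
            new = np.vstack([pts[:1], segs.reshape(-1, 3)])
            step = trace.step_len / m if trace.step_len else None
            return FiberTrace(new, step_len=step, meta=dict(trace.meta))
        f = int(round(factor))
        if abs(factor - f) < 1e-6 and f >= 2:
            new = pts[::f]
            if new.shape[0] < 2:
                raise ValueError(
                    f"factor {f} leaves fewer than 2 points")
            return FiberTrace(new, step_len=None, meta=dict(trace.meta))
        raise ValueError(
            f"subdivide_subsample requires a factor of the form 1/m, 1, or "
            f"an integer; got {factor}")

    if mode == "renudge":
        if trace.step_len is None:
            raise ValueError("renudge requires a trace with a native step")
        return nudge_trace(trace, factor * trace.step_len)

    raise ValueError(f"unknown mode {mode!r}")


def kappa_step_curve(traces: Sequence[FiberTrace],
                     factors: Sequence[float] = DEFAULT_FACTORS,
                     mode: str = "subdivide_subsample",
                     method: str = "approx3d") -> StepKappaCurve:
    """Estimate kappa for every trace at every step multiplier.

    Traces too short for a factor (fewer than 3 points after resampling, or
    shorter than the renudge step) are skipped with a logged warning and
    enter the curve as NaN; a factor at which *every* trace is skipped is an
    error.  Degenerate traces (perfectly straight, L = 1) also yield NaN.
    """
    factors = np.asarray(sorted(factors), float)
    kappas = np.full((factors.size, len(traces)), np.nan)
    for i, f in enumerate(factors):
        ok = 0
        for j, tr in enumerate(traces):
            try:
                rs = resample_trace(tr, float(f), mode)
                sample = standardize_steps(rs)
                native = tr.step_len if tr.step_len else float("nan")
                est = estimate_kappa(sample, method=method,
                                     step_len=f * native)
                kappas[i, j] = est.kappa
                ok += 1
            except ValueError as exc:
                logger.warning("trace %d skipped at factor %g: %s", j, f, exc)
        if ok == 0:
            raise ValueError(f"all traces skipped at factor {f:g}")
    return StepKappaCurve(factors=factors, kappa_per_fiber=kappas, mode=mode)


def find_inflection(curve: StepKappaCurve):
    """Locate the elbow of the kappa-vs-step curve.

    Works on log kappa versus log factor (both axes span about an order of
    magnitude), estimating the discrete second derivative at every interior
    factor on the possibly non-uniform log grid and returning the factor
    that maximizes it, together with the full second-difference profile so
    that an "inflection region" can be judged rather than a single point.

    Raises when the curve has no detectable curvature (maximal second
    difference below 10% of the curve's log-range).
    """
    f = curve.factors
    if f.size < 5:
        raise ValueError("need at least 5 factors to locate an inflection")
    y = np.log(curve.kappa_mean)
    x = np.log(f)
    if not np.all(np.isfinite(y)):
        raise ValueError("curve contains undefined kappa values")
    d2 = np.full(f.size, np.nan)
    for i in range(1, f.size - 1):
        sl = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        sr = (y[i] - y[i - 1]) / (x[i] - x[i - 1])
        d2[i] = 2.0 * (sl - sr) / (x[i + 1] - x[i - 1])
    rng = float(y.max() - y.min())
    peak = np.nanmax(d2)
    if rng <= 0 or peak < 0.1 * rng:
        raise ValueError("no detectable inflection: curve is monotone-flat")
    best = float(f[int(np.nanargmax(d2))])
    return best, d2
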