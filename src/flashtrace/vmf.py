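"""von Mises-Fisher directional statistics on the unit sphere.

The trajectory model treats each fiber step as a unit vector drawn from the
von Mises-Fisher (vMF) distribution with mean direction equal to the previous
step and a fixed concentration parameter kappa (> 0).  Low kappa gives a
flexible, tortuous fiber; high kappa a rigid, straight one.  This module
provides:

* exact vMF sampling about an arbitrary mean direction (Wood's construction:
  sample about the pole ``mu0 = (0, 0, 1)``, then rotate);
* the closed-form rotation matrix taking ``mu0`` to any mean direction;
* step standardization -- iteratively rotating a trajectory so the current
  step maps to ``mu0``, turning successive step directions into a single
  spherical sample;
* kappa estimation from the mean resultant length L of that sample.

All estimators are based on ``A(kappa) = coth(kappa) - 1/kappa``, the mean
resultant length of the 3D vMF distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .trajectory import FiberTrace

__all__ = [
    "MU0",
    "DirectionSample",
    "KappaEstimate",
    "rotation_to",
    "sample_vmf",
    "standardize_steps",
    "estimate_kappa",
    "vmf_mean_resultant_length",
]

#: the reference pole about which vMF samples are generated before rotation
MU0 = np.array([0.0, 0.0, 1.0])

_UNIT_TOL = 1e-9
_ANTIPODAL_EPS = 1e-6


def _check_unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit vector (norm {n:.3g})")
    return v


@dataclass
class DirectionSample:
    """A collection of unit direction vectors and its resultant summary."""

    directions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("all directions must be unit vectors")
        self.directions = d

    def __len__(self) -> int:
        return self.directions.shape[0]

    @property
    def mean_vector(self) -> np.ndarray:
        return self.directions.mean(axis=0)

    @property
    def L(self) -> float:
        """Mean resultant length: norm of the arithmetic mean direction.

        L -> 1 for perfectly aligned directions (an "infinitely rigid"
        fiber), L -> 0 for uniformly scattered directions.
        """
        return float(np.linalg.norm(self.mean_vector))

    def to_csv(self, path: str | Path) -> None:
        header = "ux,uy,uz"
        np.savetxt(path, self.directions, delimiter=",", header=header,
                   comments="", fmt="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DirectionSample":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr)


@dataclass
class KappaEstimate:
    """A concentration-parameter estimate tagged with its sampling step.

    Estimates are only comparable at the same sampling step, so the step at
    which kappa was computed is carried alongside the value -- e.g. report
    "kappa(1.5 um) = 20", never a bare number.
    """

    kappa: float
    method: str  # approx3d | simple | fixed_point
    step_len: float
    n_directions: int
    L: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_directions < 2:
            raise ValueError("an estimate needs at least 2 directions")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kappa": self.kappa,
            "method": self.method,
            "step_len_um": self.step_len,
            "n_directions": self.n_directions,
            "L": self.L,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "KappaEstimate":
        d = json.loads(text)
        return cls(kappa=d["kappa"], method=d["method"],
                   step_len=d["step_len_um"], n_directions=d["n_directions"],
                   L=d["L"])


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def rotation_to(mu: np.ndarray) -> np.ndarray:
    """Rotation matrix M with ``M @ (0, 0, 1) == mu``.

    Closed form in the components of ``mu``; the third column of M is ``mu``
    itself and M is a proper rotation (orthogonal, det +1).  The closed form
    divides by ``1 + mu3`` and is singular at the antipode ``(0, 0, -1)``;
    there the exact 180-degree rotation about the x-axis, diag(1, -1, -1),
    is substituted.  (Step directions of a physical fiber cannot point back
    exactly at the previous point, so the antipodal case only arises from
    numerical noise.)
    """
    mu = _check_unit(mu, "mu")
    return _rotation_matrices(mu[None, :])[0]


def _rotation_matrices(mu: np.ndarray) -> np.ndarray:
    """Vectorized ``rotation_to`` for an (n, 3) array of unit vectors."""
    m1, m2, m3 = mu[:, 0], mu[:, 1], mu[:, 2]
    n = mu.shape[0]
    M = np.empty((n, 3, 3))
    safe = m3 > -1.0 + _ANTIPODAL_EPS
    d = np.where(safe, 1.0 + m3, 1.0)
    M[:, 0, 0] = m3 + m2 ** 2 / d
    M[:, 0, 1] = -m1 * m2 / d
    M[:, 0, 2] = m1
    M[:, 1, 0] = -m1 * m2 / d
    M[:, 1, 1] = 1.0 - m2 ** 2 / d
    M[:, 1, 2] = m2
    M[:, 2, 0] = -m1
    M[:, 2, 1] = -m2
    M[:, 2, 2] = m3
    if not np.all(safe):
        M[~safe] = np.diag([1.0, -1.0, -1.0])
    return M


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_pole_frame(kappa: float, count: int, rng: np.random.Generator
                       ) -> np.ndarray:
    """vMF draws about the pole (0, 0, 1) via Wood's construction.

    A planar unit vector v is uniform on the circle; the polar component w on
    [-1, 1] has density proportional to exp(kappa * w) and is drawn by exact
    inverse-CDF: w = 1 + log(xi + (1 - xi) exp(-2 kappa)) / kappa with xi
    uniform on (0, 1).  The sample is (v * sqrt(1 - w^2), w).
    """
    xi = rng.random(count)
    # keep xi strictly positive so log() stays finite when exp(-2k) underflows
    xi = np.clip(xi, 1e-300, None)
    w = 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    theta = rng.uniform(0.0, 2.0 * np.pi, count)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), w])


def sample_vmf_rng(mu: np.ndarray, kappa: float, count: int,
                   rng: np.random.Generator) -> np.ndarray:
    """vMF draws about ``mu`` using an existing generator; returns (n, 3)."""
    mu = _check_unit(mu, "mu")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if count < 1:
        raise ValueError("count must be >= 1")
    u0 = _sample_pole_frame(kappa, count, rng)
    M = rotation_to(mu)
    return u0 @ M.T


def sample_vmf(mu: np.ndarray, kappa: float, count: int,
               seed: int) -> DirectionSample:
    """Draw ``count`` unit vectors from vMF(mu, kappa), deterministic per seed."""
    rng = np.random.default_rng(seed)
    return DirectionSample(sample_vmf_rng(mu, kappa, count, rng))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_steps(trace: FiberTrace) -> DirectionSample:
    """Reduce a trajectory to a single spherical sample of step directions.

    Each step is rotated so that the *previous* step direction coincides with
    the pole (0, 0, 1); the rotated next-step direction is recorded.  A trace
    of n points yields n - 2 standardized directions.  The output is
    invariant under any global rigid rotation or translation of the trace,
    which is what makes fibers with different absolute orientations
    comparable.
    """
    pts = trace.points
    if pts.shape[0] < 3:
        raise ValueError("insufficient steps: need at least 3 points")
    steps = np.diff(pts, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    if np.any(norms == 0.0):
        idx = int(np.argmin(norms))
        raise ValueError(f"zero-length step at index {idx}")
    dirs = steps / norms[:, None]
    M = _rotation_matrices(dirs[:-1])
    # standardized direction = M^-1 @ next = M^T @ next
    std = np.einsum("nij,ni->nj", M, dirs[1:])
    # renormalize against accumulated rounding
    std /= np.linalg.norm(std, axis=1)[:, None]
    return DirectionSample(std)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def vmf_mean_resultant_length(kappa: float) -> float:
    """A(kappa) = coth(kappa) - 1/kappa, the population mean resultant length."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if kappa < 1e-4:
        # series: kappa/3 - kappa^3/45, avoids catastrophic cancellation
        return kappa / 3.0 - kappa ** 3 / 45.0
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


_METHODS = ("approx3d", "simple", "fixed_point")


def estimate_kappa(sample: DirectionSample, method: str = "approx3d",
                   step_len: float = float("nan")) -> KappaEstimate:
    """Estimate the vMF concentration parameter from a direction sample.

    Methods (all driven by the mean resultant length L of the sample):

    ``approx3d``
        L (3 - L^2) / (1 - L^2); accurate over the whole range and the
        package default.
    ``simple``
        1 / (1 - L); valid only for L >= 0.9, i.e. for kappa estimates
        above 10 -- the regime of stiff axons.
    ``fixed_point``
        the exact moment estimator, solving A(kappa) = L.

    ``step_len`` records the sampling step (um) the directions were obtained
    at; estimates are meaningless without it.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    n = len(sample)
    if n < 2:
        raise ValueError("need at least 2 directions")
    L = sample.L
    if L >= 1.0 - 1e-12:
        raise ValueError("degenerate: infinitely rigid fiber (L = 1)")
    if L <= 0.0:
        raise ValueError("L = 0: no preferred direction, kappa undefined")

    if method == "approx3d":
        kappa = L * (3.0 - L * L) / (1.0 - L * L)
    elif method == "simple":
        if L < 0.9:
            raise ValueError(
                f"simple estimator 1/(1-L) requires L >= 0.9 (got L={L:.4f}); "
                "it is only valid for kappa > 10"
            )
        kappa = 1.0 / (1.0 - L)
    else:  # fixed_point
        hi = max(1e4, 10.0 / (1.0 - L))
        kappa = float(brentq(lambda k: vmf_mean_resultant_length(k) - L,
                             1e-9, hi, xtol=1e-9, rtol=8.9e-16))

    return KappaEstimate(kappa=float(kappa), method=method,
                         step_len=step_len, n_directions=n, L=L)
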