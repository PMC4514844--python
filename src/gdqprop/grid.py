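"""Diffusion-specific interpolation grid.

The exact profile after any on/off source history is a sum of the basis
functions

    e_0(R) = erfc(R),   e_m(R) = erf(R/sqrt(m)) - erf(R/sqrt(m+1))  (m >= 1),

so a grid that interpolates every e_m well interpolates every reachable
profile well.  The domain [0, R_max] is split at R = 10 into a linearly
seeded near interval (where e_1 has all its structure) and a
logarithmically seeded far interval, and each seeded subinterval is
bisected until cubic interpolation reproduces e_m at the midpoint to a
tolerance, for a sweep of m values up to m_max.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfc

from .fornberg import interpolate

__all__ = ["InterpolationGrid", "e_m", "solve_rmax", "build_grid",
           "save_grid", "load_grid", "NEAR_FAR_SPLIT"]

#: boundary between the linearly and logarithmically seeded intervals
NEAR_FAR_SPLIT = 10.0

#: m values swept during refinement: every small m (most structure) and a
#: sparse sample of large m, which add little
_M_SWEEP = list(range(21)) + [30, 50, 100, 200, 500]

_MAX_BISECTIONS = 40
_REFINE_NF = 4  # cubic midpoint check


@dataclass
class InterpolationGrid:
    points: np.ndarray
    I_near: int
    I_far: int
    R_max: float
    tol: float
    m_max: int

    @property
    def I(self) -> int:  # noqa: E743 - field name from the algorithm
        return self.points.size

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if pts[0] != 0.0:
            raise ValueError("grid must start at R = 0")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if not math.isclose(pts[-1], self.R_max, rel_tol=1e-12):
            raise ValueError("grid must end at R_max")
        if self.I_near + self.I_far != pts.size:
            raise ValueError("I_near + I_far must equal the point count")
        self.points = pts


def e_m(R, m: int):
    """Basis function of the exact random-history solution."""
    if m < 0:
        raise ValueError("m must be >= 0")
    R = np.asarray(R, float)
    if m == 0:
        out = erfc(R)
    else:
        out = erf(R / math.sqrt(m)) - erf(R / math.sqrt(m + 1))
    return float(out) if out.ndim == 0 else out


def solve_rmax(F_max: float, eps: float, n_steps_max: int) -> float:
    """Outer boundary where the worst-case (always-on) profile drops to eps.

    Solves F_max * erfc(R / sqrt(n_steps_max)) = eps * R by bracketed
    bisection; n_steps_max = 1 recovers the single-step criterion.  The
    left side is decreasing and the right increasing, so the root is unique.
    """
    if F_max <= 0 or eps <= 0:
        raise ValueError("F_max and eps must be positive")
    if n_steps_max < 1:
        raise ValueError("n_steps_max must be >= 1")
    scale = math.sqrt(n_steps_max)

    def f(R):
        return F_max * erfc(R / scale) - eps * R

    lo, hi = 1e-6, 1e9
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValueError("no sign change in bracket [1e-6, 1e9]")
    return float(brentq(f, lo, hi, rtol=1e-9))


def _seed_points(R_max: float, near_base: int, far_base: int) -> np.ndarray:
    near = np.linspace(0.0, NEAR_FAR_SPLIT, near_base)
    far = np.logspace(math.log10(NEAR_FAR_SPLIT), math.log10(R_max),
                      far_base + 1)[1:]
    far[-1] = R_max
    return np.concatenate([near, far])


def build_grid(R_max: float, near_base: int, far_base: int,
               tol: float = math.inf, m_max: int = 500) -> InterpolationGrid:
    """Seed the near/far grid and refine by midpoint bisection against e_m.

    With tol = inf (prescribed-counts mode, used for parameter sweeps) the
    seeded ``near_base + far_base`` points are returned as-is.  Otherwise
    subintervals are bisected until the cubic interpolant of every swept
    e_m matches the midpoint value within tol; the final grid certifies
    this for all swept m simultaneously.
    """
    if R_max <= NEAR_FAR_SPLIT:
        raise ValueError(f"R_max must exceed the near/far split {NEAR_FAR_SPLIT}")
    if near_base < 2 or far_base < 2:
        raise ValueError("near_base and far_base must be >= 2")
    pts = set(_seed_points(R_max, near_base, far_base).tolist())
    if math.isfinite(tol):
        ms = [m for m in _M_SWEEP if m <= m_max]
        if m_max not in ms:
            ms.append(m_max)
        while True:
            added_any = False
            for m in ms:
                depth = 0
                while True:
                    arr = np.array(sorted(pts))
                    vals = e_m(arr, m)
                    mids = 0.5 * (arr[:-1] + arr[1:])
                    approx = np.array([
                        interpolate(vals, arr, x, _REFINE_NF) for x in mids])
                    bad = mids[np.abs(e_m(mids, m) - approx) > tol]
                    if bad.size == 0:
                        break
                    depth += 1
                    if depth > _MAX_BISECTIONS:
                        raise RuntimeError(
                            f"bisection depth > {_MAX_BISECTIONS} for m={m}: "
                            "tolerance unattainable")
                    pts.update(bad.tolist())
                    added_any = True
            if not added_any:
                break
    arr = np.array(sorted(pts))
    I_near = int(np.sum(arr <= NEAR_FAR_SPLIT))
    return InterpolationGrid(points=arr, I_near=I_near,
                             I_far=arr.size - I_near, R_max=float(R_max),
                             tol=float(tol), m_max=int(m_max))


def save_grid(path, grid: InterpolationGrid) -> None:
    with open(path, "w") as fh:
        json.dump({
            "R_max": f"{grid.R_max:.17g}",
            "tol": repr(grid.tol),
            "m_max": grid.m_max,
            "I_near": grid.I_near,
            "I_far": grid.I_far,
            "points": [f"{x:.17g}" for x in grid.points],
        }, fh, indent=1)


def load_grid(path) -> InterpolationGrid:
    with open(path) as fh:
        rec = json.load(fh)
    return InterpolationGrid(
        points=np.array([float(x) for x in rec["points"]]),
        I_near=int(rec["I_near"]), I_far=int(rec["I_far"]),
        R_max=float(rec["R_max"]), tol=float(rec["tol"]),
        m_max=int(rec["m_max"]))
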