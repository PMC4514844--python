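"""Closed-form solutions, nondimensionalization and unit conversions.

All of the algorithm's internal arithmetic is dimensionless: radii are
scaled by the diffusion length 2*sqrt(D*dt) and the profile variable is
rho(R) = R * c(r).  A single on-interval of the point source adds
F * erfc(R) to rho, with the flux factor

    F = j / (geometry_factor * 2 * D^{3/2} * dt^{1/2})

in number density (geometry_factor = 4*pi for full space, 2*pi for a
source on a membrane half-space).  The exact profile after any on/off
history is the history sum over the e_m basis functions; with the source
always on it telescopes to F * erfc(R / sqrt(k)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .grid import e_m

__all__ = ["AVOGADRO", "CONC_UNITS", "PhysicalParams", "SourceHistory",
           "flux_factor", "always_on_profile", "exact_profile",
           "to_physical", "nondimensionalize", "convert_concentration"]

AVOGADRO = 6.02214076e23

#: multiply a number density (m^-3) by these factors to convert
CONC_UNITS = {
    "m^-3": 1.0,
    "M": 1.0 / (AVOGADRO * 1e3),
    "mM": 1e3 / (AVOGADRO * 1e3),
    "uM": 1e6 / (AVOGADRO * 1e3),
    "nM": 1e9 / (AVOGADRO * 1e3),
}

FULL_SPACE = 4.0 * math.pi
HALF_SPACE = 2.0 * math.pi


def convert_concentration(value, from_unit: str, to_unit: str):
    """Convert concentrations through the number-density constants table."""
    return value * (CONC_UNITS[to_unit] / CONC_UNITS[from_unit])


@dataclass
class PhysicalParams:
    """Physical configuration of a point-source diffusion run.

    D in m^2/s, dt in s, j in particles/s, c0 in the unit named by
    ``c0_unit`` (default number density).
    """

    D: float
    dt: float
    j: float = 0.0
    c0: float = 0.0
    c0_unit: str = "m^-3"
    geometry_factor: float = FULL_SPACE

    def __post_init__(self):
        if self.D <= 0 or self.dt <= 0:
            raise ValueError("D and dt must be positive")
        if self.c0_unit not in CONC_UNITS:
            raise ValueError(f"unknown concentration unit {self.c0_unit!r}")

    @property
    def diffusion_length(self) -> float:
        """2*sqrt(D*dt), the length scale that nondimensionalizes r."""
        return 2.0 * math.sqrt(self.D * self.dt)

    def c0_in(self, unit: str) -> float:
        return convert_concentration(self.c0, self.c0_unit, unit)


@dataclass
class SourceHistory:
    """Realized source record: chi_n in {0,1} and flux factors F_n >= 0."""

    chi: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        self.chi = np.asarray(self.chi)
        self.F = np.broadcast_to(np.asarray(self.F, float),
                                 self.chi.shape).copy()
        if not np.isin(self.chi, (0, 1)).all():
            raise ValueError("chi values must be 0 or 1")
        if np.any(self.F < 0):
            raise ValueError("flux factors must be >= 0")

    def __len__(self) -> int:
        return self.chi.size

    @classmethod
    def constant(cls, n: int, F: float = 1.0) -> "SourceHistory":
        return cls(np.ones(n, dtype=np.int8), np.full(n, F))


def flux_factor(params: PhysicalParams, j: float | None = None,
                unit: str = "m^-3") -> float:
    """Flux factor F such that one on-interval adds F*erfc(R) to rho."""
    if j is None:
        j = params.j
    if j < 0:
        raise ValueError("flux must be >= 0")
    F = j / (params.geometry_factor * 2.0 * params.D ** 1.5
             * math.sqrt(params.dt))
    return convert_concentration(F, "m^-3", unit)


def always_on_profile(R, k: int, F: float = 1.0):
    """rho after k completed on-steps: F*erfc(R/sqrt(k)) (0 for k = 0)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    R = np.asarray(R, float)
    out = np.zeros(R.shape) if k == 0 else F * erfc(R / math.sqrt(k))
    return float(out) if out.ndim == 0 else out


def exact_profile(R, history: SourceHistory):
    """rho_n(R) = sum_m chi_{n-m} F_{n-m} e_m(R); O(n) per evaluation.

    This is the per-step oracle for validation, not the production path.
    """
    n = len(history)
    if n == 0:
        raise ValueError("history must be nonempty")
    R = np.asarray(R, float)
    out = np.zeros(R.shape)
    chi, F = history.chi, history.F
    for m in range(n):
        coeff = chi[n - 1 - m] * F[n - 1 - m]
        if coeff:
            out += coeff * e_m(R, m)
    return float(out) if out.ndim == 0 else out


def to_physical(rho, R, params: PhysicalParams, unit: str = "m^-3"):
    """Map a nondimensional profile to (r, c(r)) in the requested unit.

    r = 2*sqrt(D*dt) * R and c = rho/R; at R = 0 the limit of rho/R is
    reported by linear extrapolation from the two innermost nonzero grid
    points (c itself diverges at an active point source).
    """
    R = np.asarray(R, float)
    rho = np.asarray(rho, float)
    r = params.diffusion_length * R
    c = np.empty_like(rho)
    nz = R > 0
    c[nz] = rho[nz] / R[nz]
    if np.any(~nz):
        inner = np.flatnonzero(nz)[:2]
        if inner.size < 2:
            raise ValueError("need two nonzero grid points to extrapolate c(0)")
        (i1, i2) = inner
        c1, c2 = rho[i1] / R[i1], rho[i2] / R[i2]
        c[~nz] = (c1 * R[i2] - c2 * R[i1]) / (R[i2] - R[i1])
    return r, convert_concentration(c, "m^-3", unit)


def nondimensionalize(c, r, params: PhysicalParams, unit: str = "m^-3"):
    """Inverse of :func:`to_physical` on sampled profiles: (R, rho)."""
    r = np.asarray(r, float)
    c_m3 = convert_concentration(np.asarray(c, float), unit, "m^-3")
    R = r / params.diffusion_length
    return R, R * c_m3
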