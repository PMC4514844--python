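"""Propagation-matrix assembly and time stepping.

One time step of the nondimensional profile rho is the sparse update

    rho_{n+1} = W rho_n + chi_n F_n s,        s_i = erfc(R_i),

where the combined weight W_ij = sum_a A_j(x_a(R_i)) w_a(R_i) folds the
R_i-dependent Gauss-diffusion quadrature into the Fornberg interpolation
stencils at the quadrature points.  The step is an exact solution of the
diffusion equation over dt up to quadrature/interpolation error, so dt can
be arbitrarily large (unconditional stability); dt enters only through the
nondimensionalization, never through W.

Row 0 (R = 0) of W is identically zero because W(0, .) == 0, while
s_0 = erfc(0) = 1, so rho(0) = chi_n F_n each step - the correct limit
R*c(R) -> chi j/(4 pi D) * 2 sqrt(D dt) of the source profile.

The high-buffer reaction extension multiplies the propagated part by
(1 - k_on*b*dt) (one-point time quadrature of the binding sink) and adds
the uniform unbinding source k_off*B*dt, whose nondimensional form is
k_off*B*dt * R_i since the heat kernel integrates to exactly 1 over R^3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.special import erfc

from .exact import PhysicalParams, SourceHistory, flux_factor
from .fornberg import fornberg_weights, select_stencil
from .gdq import DEFAULT_PRECISION_DIGITS, cached_gdq
from .grid import InterpolationGrid

__all__ = [
    "PropagationMatrix", "SimulationState", "ReactionParams", "Trajectory",
    "DivergenceError", "assemble", "step", "step_reaction", "run",
    "AlwaysOnSource", "ScheduleSource", "BernoulliSource",
    "ThresholdFeedbackSource", "save_matrix", "load_matrix",
    "DIVERGENCE_THRESHOLD",
]

#: |rho|/F beyond which the iteration is declared divergent
DIVERGENCE_THRESHOLD = 1e10

#: combined weights below this fraction of the row maximum are dropped
DROP_TOL = 1e-16


class DivergenceError(RuntimeError):
    def __init__(self, step_index: int):
        super().__init__(
            f"simulation diverged at step {step_index} (|rho|/F > "
            f"{DIVERGENCE_THRESHOLD:g}); small changes in N and N_F usually "
            "alleviate this")
        self.step_index = step_index


@dataclass
class PropagationMatrix:
    W: sparse.csr_matrix
    s: np.ndarray
    grid: InterpolationGrid
    N: int
    NF: int
    _dense: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def nnz(self) -> int:
        return int(self.W.nnz)

    @property
    def dense(self) -> np.ndarray:
        """Dense copy used for fast stepping of small systems."""
        if self._dense is None:
            self._dense = self.W.toarray()
        return self._dense


@dataclass
class ReactionParams:
    """High-buffer limit: fixed free (b) and bound (B) buffer concentrations."""

    k_on: float
    k_off: float
    b_free: float
    B_bound: float

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.b_free, self.B_bound) < 0:
            raise ValueError("reaction parameters must be >= 0")


@dataclass
class SimulationState:
    rho: np.ndarray
    step: int = 0
    chi_history: list = field(default_factory=list)
    F_history: list = field(default_factory=list)

    @property
    def history(self) -> SourceHistory:
        return SourceHistory(np.array(self.chi_history, dtype=np.int8),
                             np.array(self.F_history, float))


def assemble(grid: InterpolationGrid, N: int, NF: int,
             precision_digits: int = DEFAULT_PRECISION_DIGITS) -> PropagationMatrix:
    """Build the combined-weight matrix W and source vector s on a grid.

    For each grid point R_i > 0 an N-point GDQ rule is built (and cached),
    every quadrature point is resolved to its NF-point Fornberg stencil,
    and the products A_j * w_a accumulate into row i.  Quadrature points
    beyond R_max use the boundary-clamped stencil (the profile there is
    ~0 by construction of R_max).
    """
    pts = grid.points
    I = pts.size
    if NF > I:
        raise ValueError("NF exceeds grid size")
    if N < 1:
        raise ValueError("N must be >= 1")
    rows, cols, vals = [], [], []
    overshoot = 0.0
    for i in range(1, I):
        rule = cached_gdq(pts[i], N, precision_digits)
        overshoot = max(overshoot, rule.points[-1] / grid.R_max)
        row = np.zeros(I)
        for x, w in zip(rule.points, rule.weights):
            idx = select_stencil(x, pts, NF)
            row[idx] += w * fornberg_weights(x, pts[idx])
        keep = np.abs(row) >= DROP_TOL * np.abs(row).max()
        idx = np.flatnonzero(keep)
        rows.extend([i] * idx.size)
        cols.extend(idx.tolist())
        vals.extend(row[idx].tolist())
    if overshoot > 1.1:
        warnings.warn(
            f"quadrature points exceed R_max by {100 * (overshoot - 1):.0f}% "
            "- the interpolation domain may be too small", stacklevel=2)
    W = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(I, I))
    return PropagationMatrix(W=W, s=erfc(pts), grid=grid, N=N, NF=NF)


def _check_divergence(rho: np.ndarray, F_scale: float, step_index: int) -> None:
    m = float(np.max(np.abs(rho))) if rho.size else 0.0
    if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD * max(F_scale, 1e-300):
        raise DivergenceError(step_index)


def step(state: SimulationState, P: PropagationMatrix, chi: int,
         F: float) -> SimulationState:
    """Advance one diffusion step: rho <- W rho + chi F s."""
    if state.rho.size != P.grid.I:
        raise ValueError("state length does not match the grid")
    rho = P.dense @ state.rho + (chi * F) * P.s
    chi_hist = state.chi_history + [int(chi)]
    F_hist = state.F_history + [float(F)]
    _check_divergence(rho, max(F_hist, default=1.0) or 1.0, state.step + 1)
    return SimulationState(rho=rho, step=state.step + 1,
                           chi_history=chi_hist, F_history=F_hist)


def step_reaction(state: SimulationState, P: PropagationMatrix, chi: int,
                  F: float, rp: ReactionParams, dt: float,
                  buffer_source_multiplier: float = 1.0) -> SimulationState:
    """Advance one buffered reaction-diffusion step.

    rho <- (1 - k_on b dt) W rho + chi F s + mult * k_off B dt * R.
    The default multiplier 1 is the kernel-normalized unbinding source.
    Requires k_on*b*dt < 1 so the explicit binding factor is a contraction.
    """
    kb = rp.k_on * rp.b_free * dt
    if kb >= 1.0:
        raise ValueError("k_on * b_free * dt must be < 1 for the explicit "
                         "reaction factor to be a contraction")
    unbind = buffer_source_multiplier * rp.k_off * rp.B_bound * dt
    rho = (1.0 - kb) * (P.dense @ state.rho) + (chi * F) * P.s \
        + unbind * P.grid.points
    chi_hist = state.chi_history + [int(chi)]
    F_hist = state.F_history + [float(F)]
    _check_divergence(rho, max(max(F_hist, default=1.0), unbind) or 1.0,
                      state.step + 1)
    return SimulationState(rho=rho, step=state.step + 1,
                           chi_history=chi_hist, F_history=F_hist)


# ---------------------------------------------------------------------------
# source processes
# ---------------------------------------------------------------------------

class AlwaysOnSource:
    """Constant flux, always on."""

    def __init__(self, j: float):
        self.j = j

    def __call__(self, n, rho, rng):
        return 1, self.j


class ScheduleSource:
    """Deterministic on/off pattern with a constant (or per-step) flux."""

    def __init__(self, chi, j):
        self.chi = np.asarray(chi, int)
        self.j = np.broadcast_to(np.asarray(j, float), self.chi.shape)

    def __call__(self, n, rho, rng):
        return int(self.chi[n]), float(self.j[n])


class BernoulliSource:
    """Seeded Bernoulli(p_on) gating of a constant flux."""

    def __init__(self, p_on: float, j: float):
        if not 0.0 <= p_on <= 1.0:
            raise ValueError("p_on must be in [0, 1]")
        self.p_on = p_on
        self.j = j

    def __call__(self, n, rho, rng):
        return int(rng.random() < self.p_on), self.j


class ThresholdFeedbackSource:
    """Concentration feedback: the source switches off while the profile at a
    sensing grid index exceeds a threshold (a minimal CICR-style gate)."""

    def __init__(self, j: float, sense_index: int, threshold: float):
        self.j = j
        self.sense_index = sense_index
        self.threshold = threshold

    def __call__(self, n, rho, rng):
        return int(rho[self.sense_index] <= self.threshold), self.j


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    grid: InterpolationGrid
    steps: np.ndarray          # recorded step indices (1-based, post-step)
    times: np.ndarray          # seconds
    rho: np.ndarray            # (n_recorded, I)
    history: SourceHistory     # full per-step record
    record_every: int

    def to_csv(self, path) -> None:
        import pandas as pd
        n = self.steps.size
        df = pd.DataFrame({
            "step": self.steps,
            "t_seconds": self.times,
            "chi": self.history.chi[self.steps - 1],
        })
        for i, R in enumerate(self.grid.points):
            df[f"rho@R={R:.10g}"] = self.rho[:, i]
        df.to_csv(path, index=False)


def run(P: PropagationMatrix, params: PhysicalParams, source: Callable,
        n_steps: int, seed: int | None = None, record_every: int = 1,
        reaction: ReactionParams | None = None,
        unit: str = "m^-3") -> Trajectory:
    """Run the propagation loop from rho(R, 0) = c0 * R.

    The source process is called as ``source(n, rho, rng)`` and returns
    (chi_n, j_n); it may read the current profile (feedback gating).  All
    randomness comes from the single generator seeded with ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    state = SimulationState(rho=params.c0_in(unit) * P.grid.points)
    rec_steps, rec_times, rec_rho = [], [], []
    for n in range(n_steps):
        chi, j = source(n, state.rho, rng)
        F = flux_factor(params, j, unit=unit)
        if reaction is None:
            state = step(state, P, chi, F)
        else:
            state = step_reaction(state, P, chi, F, reaction, params.dt)
        if (n + 1) % record_every == 0 or n == n_steps - 1:
            rec_steps.append(n + 1)
            rec_times.append((n + 1) * params.dt)
            rec_rho.append(state.rho.copy())
    return Trajectory(grid=P.grid, steps=np.array(rec_steps),
                      times=np.array(rec_times), rho=np.array(rec_rho),
                      history=state.history, record_every=record_every)


# ---------------------------------------------------------------------------
# structured-text matrix cache
# ---------------------------------------------------------------------------

def save_matrix(path, P: PropagationMatrix) -> None:
    coo = P.W.tocoo()
    with open(path, "w") as fh:
        json.dump({
            "N": P.N, "NF": P.NF,
            "grid_points": [f"{x:.17g}" for x in P.grid.points],
            "I_near": P.grid.I_near, "I_far": P.grid.I_far,
            "R_max": f"{P.grid.R_max:.17g}",
            "tol": repr(P.grid.tol), "m_max": P.grid.m_max,
            "triplets": [[int(i), int(j), f"{v:.17g}"]
                         for i, j, v in zip(coo.row, coo.col, coo.data)],
        }, fh)


def load_matrix(path) -> PropagationMatrix:
    with open(path) as fh:
        rec = json.load(fh)
    pts = np.array([float(x) for x in rec["grid_points"]])
    grid = InterpolationGrid(points=pts, I_near=int(rec["I_near"]),
                             I_far=int(rec["I_far"]),
                             R_max=float(rec["R_max"]),
                             tol=float(rec["tol"]), m_max=int(rec["m_max"]))
    rows = [t[0] for t in rec["triplets"]]
    cols = [t[1] for t in rec["triplets"]]
    vals = [float(t[2]) for t in rec["triplets"]]
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(pts.size, pts.size))
    return PropagationMatrix(W=W, s=erfc(pts), grid=grid,
                             N=int(rec["N"]), NF=int(rec["NF"]))
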