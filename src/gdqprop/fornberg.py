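"""Polynomial interpolation weights on arbitrary nodes (Fornberg, M = 0).

Function-value interpolation only: given a target abscissa x0 and N_F
pairwise-distinct nodes, the recursion below produces weights A_nu with
f(x0) ~ sum_nu A_nu f(node_nu), exact for polynomials of degree <= N_F - 1.
The outer recursion runs over the N_F stencil nodes only, never the full
grid.  Stencils are the N_F grid nodes nearest to x0 and are always
contiguous in the sorted grid; distance ties extend the window toward
larger R (profiles decay outward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Stencil", "select_stencil", "fornberg_weights", "interpolate",
           "make_stencil"]


@dataclass
class Stencil:
    target: float
    node_indices: np.ndarray
    weights: np.ndarray


#: minimum stencil nodes kept on each side of the target (where the grid
#: allows).  Pure nearest-by-distance selection puts all but one node on the
#: fine side when the target falls in a locally coarse interval (e.g. the
#: first gap past the near/far spacing change); the resulting one-sided
#: high-degree stencil oscillates and can push the propagation matrix's
#: spectral radius far above 1, which is the long-run divergence mode seen
#: for large NF.  Guarding three nodes per side restores a balanced stencil
#: exactly in those gaps and is a no-op wherever spacing is locally smooth.
MIN_SIDE_NODES = 3


def select_stencil(x0: float, grid_points, NF: int) -> np.ndarray:
    """Indices of the NF grid nodes nearest x0 (contiguous, boundary-clamped).

    Distance ties extend toward larger R; a minimum per-side occupancy of
    min(MIN_SIDE_NODES, NF//2) nodes is enforced where the grid allows.
    """
    g = np.asarray(grid_points, float)
    n = g.size
    if NF > n:
        raise ValueError(f"stencil size NF={NF} exceeds grid size {n}")
    if NF < 1:
        raise ValueError("NF must be >= 1")
    j = int(np.searchsorted(g, x0))
    left, right = j - 1, j
    for _ in range(NF):
        if left < 0:
            right += 1
        elif right >= n:
            left -= 1
        else:
            # tie (equidistant) extends toward larger R
            if g[right] - x0 <= x0 - g[left]:
                right += 1
            else:
                left -= 1
    lo, hi = left + 1, right
    want = min(MIN_SIDE_NODES, NF // 2)
    n_right = hi - j
    n_left = j - lo
    if n_right < want:
        shift = min(want - n_right, n - hi)
        lo += shift
        hi += shift
    elif n_left < want:
        shift = min(want - n_left, lo)
        lo -= shift
        hi -= shift
    return np.arange(lo, hi)


def fornberg_weights(x0: float, nodes) -> np.ndarray:
    """Interpolation weights at x0 from the given nodes (degree NF-1 exact)."""
    x = np.asarray(nodes, float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one node")
    d = np.zeros((n, n))
    d[0, 0] = 1.0
    c1 = 1.0
    for k in range(1, n):
        c2 = 1.0
        for nu in range(k):
            c3 = x[k] - x[nu]
            if c3 == 0.0:
                raise ValueError("duplicate interpolation nodes")
            c2 *= c3
            d[k, nu] = (x[k] - x0) * d[k - 1, nu] / c3
        d[k, k] = -(c1 / c2) * (x[k - 1] - x0) * d[k - 1, k - 1]
        c1 = c2
    return d[n - 1].copy()


def make_stencil(x0: float, grid_points, NF: int) -> Stencil:
    idx = select_stencil(x0, grid_points, NF)
    g = np.asarray(grid_points, float)
    return Stencil(float(x0), idx, fornberg_weights(x0, g[idx]))


def interpolate(values, grid_points, x0: float, NF: int) -> float:
    """Evaluate the NF-point nearest-stencil interpolant of sampled values."""
    values = np.asarray(values, float)
    g = np.asarray(grid_points, float)
    if values.shape != g.shape:
        raise ValueError("values and grid must have the same length")
    st = make_stencil(x0, g, NF)
    return float(st.weights @ values[st.node_indices])
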