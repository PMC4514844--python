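"""Gauss-diffusion quadrature (GDQ).

The one-step propagator of the spherically-symmetric diffusion equation
reduces, after nondimensionalizing with the diffusion length 2*sqrt(D*dt),
to a 1-D integral against the kernel

    W(R, R') = (1/sqrt(pi)) * [exp(-(R-R')^2) - exp(-(R+R')^2)]
             = (2/sqrt(pi)) * exp(-R^2 - R'^2) * sinh(2 R R')

over R' in (0, inf).  This module builds, for any evaluation radius R > 0,
the N-point Gaussian quadrature whose weight function is W(R, .):

1. moments M_n = int x^n W(R,x) dx from closed-form seeds plus parity-split
   recurrences of the confluent hypergeometric function Phi(a, 3/2; R^2);
2. three-term recurrence coefficients (a_j, b_j) of the monic orthogonal
   polynomials, via coefficient-list convolutions dotted with the moment
   vector;
3. quadrature points as the roots of p_N (the eigenvalues of the associated
   symmetric tridiagonal Jacobi matrix), refined by safeguarded Newton at
   working precision from double-precision seeds, and weights from the
   Christoffel function w = 1 / sum_j p_j(x)^2 / <p_j^2> (identical to the
   squared first eigenvector component times erf(R)).

The moments-to-coefficients map is catastrophically ill-conditioned (the
monomial-basis inner products cancel roughly 2*N*log10(R) digits), so all of
steps 1-3 run in mpmath arbitrary precision and the finished rule is downcast
to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from mpmath import mp, mpf
from scipy.linalg import eigh_tridiagonal

__all__ = [
    "PrecisionExhaustedError",
    "MomentTable",
    "RecurrenceCoefficients",
    "QuadratureRule",
    "weight_function",
    "moment_table",
    "recurrence_coefficients",
    "build_gdq",
    "save_rules",
    "load_rules",
    "clear_rule_cache",
]

_SQRT_PI = math.sqrt(math.pi)

#: below this value of 2*R*R' the difference of Gaussians cancels
#: catastrophically and the sinh form is used instead
_SINH_SWITCH = 1e-4

DEFAULT_PRECISION_DIGITS = 120
MAX_PRECISION_DIGITS = 480


class PrecisionExhaustedError(RuntimeError):
    """Raised when round-off collapse makes a squared norm non-positive."""


# ---------------------------------------------------------------------------
# weight function
# ---------------------------------------------------------------------------

def weight_function(R, Rp):
    """Diffusion kernel W(R, R') of the 1-D reduced propagation integral.

    Antisymmetric in each argument; identically zero at R = 0.  Switches to
    the exp*sinh form when 2*R*R' < 1e-4 to avoid cancellation between the
    two Gaussians.
    """
    R, Rp = np.broadcast_arrays(np.asarray(R, float), np.asarray(Rp, float))
    prod = 2.0 * R * Rp
    small = np.abs(prod) < _SINH_SWITCH
    out = np.empty(R.shape, float)
    big = ~small
    out[big] = (np.exp(-(R[big] - Rp[big]) ** 2)
                - np.exp(-(R[big] + Rp[big]) ** 2)) / _SQRT_PI
    out[small] = (2.0 / _SQRT_PI) * np.exp(-(R[small] ** 2 + Rp[small] ** 2)) \
        * np.sinh(prod[small])
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

@dataclass
class MomentTable:
    """Moments M_n = int_0^inf x^n W(R, x) dx at arbitrary precision."""

    R: float
    n_max: int
    M: list  # mpf values, length n_max + 1
    precision_digits: int


def moment_table(R: float, n_max: int, precision_digits: int = 60) -> MomentTable:
    """Moments of the diffusion kernel by parity-split recurrences.

    Seeds: M_0 = erf(R), M_1 = R,
    M_2 = (R^2 + 1/2) erf(R) + R exp(-R^2)/sqrt(pi), M_3 = R(2R^2+3)/2.
    For k, l >= 2:
        M_{2k}   = (R^2 + 2k - 3/2) M_{2k-2} + (k-1)(3/2-k) M_{2k-4}
        M_{2l+1} = (R^2 + 2l - 1/2) M_{2l-1} - (l-1/2)(l-1) M_{2l-3}
    """
    if R <= 0:
        raise ValueError(
            "moment_table requires R > 0; at R = 0 the measure is degenerate "
            "(all moments vanish) and no quadrature rule exists")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if precision_digits < 50:
        raise ValueError("precision_digits must be >= 50")
    with mp.workdps(precision_digits):
        Rm = mpf(R)
        sq = Rm * Rm
        erfR = mp.erf(Rm)
        gauss = mp.exp(-sq) / mp.sqrt(mp.pi)
        seeds = [
            erfR,
            Rm,
            (sq + mpf(1) / 2) * erfR + Rm * gauss,
            Rm * (2 * sq + 3) / 2,
        ]
        M = seeds[: n_max + 1]
        for n in range(4, n_max + 1):
            if n % 2 == 0:
                k = n // 2
                M.append((sq + 2 * k - mpf(3) / 2) * M[n - 2]
                         + (k - 1) * (mpf(3) / 2 - k) * M[n - 4])
            else:
                ell = (n - 1) // 2
                M.append((sq + 2 * ell - mpf(1) / 2) * M[n - 2]
                         - (ell - mpf(1) / 2) * (ell - 1) * M[n - 4])
    return MomentTable(float(R), n_max, M, precision_digits)


# ---------------------------------------------------------------------------
# orthogonal-polynomial recurrence coefficients
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceCoefficients:
    """Monic three-term recurrence p_{j+1} = (x - a_j) p_j - b_j p_{j-1}.

    ``sq_norms[j]`` is <p_j^2> and ``poly_coeffs[j]`` the ascending
    coefficient list of p_j; both are needed for the Christoffel weights.
    """

    R: float
    N: int
    a: list          # mpf, length N
    b: list          # mpf, length N - 1 (b_1 .. b_{N-1}), all > 0
    sq_norms: list   # mpf, length N
    poly_coeffs: list
    precision_digits: int


def _conv(p: list, q: list) -> list:
    out = [mpf(0)] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi:
            for j, qj in enumerate(q):
                out[i + j] += pi * qj
    return out


def _dot_moments(coeffs: list, M: list):
    return sum((c * M[i] for i, c in enumerate(coeffs) if c), mpf(0))


def recurrence_coefficients(moments: MomentTable, N: int) -> RecurrenceCoefficients:
    """Coefficients a_j = <x p_j^2>/<p_j^2>, b_j = <p_j^2>/<p_{j-1}^2>.

    Inner products are formed by convolving coefficient lists and dotting
    with the moment vector, all at the moment table's working precision.
    Raises :class:`PrecisionExhaustedError` when a squared norm comes out
    non-positive (round-off collapse; retry at higher precision).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if moments.n_max < 2 * N:
        raise ValueError("moment table must extend to n_max >= 2N")
    if moments.precision_digits < 100:
        raise ValueError("recurrence coefficients require >= 100 working digits")
    with mp.workdps(moments.precision_digits):
        M = moments.M
        a, b, norms, polys = [], [], [], []
        p_prev = [mpf(0)]
        p_cur = [mpf(1)]
        s0_prev = None
        for j in range(N):
            sq = _conv(p_cur, p_cur)
            s0 = _dot_moments(sq, M)
            if s0 <= 0:
                raise PrecisionExhaustedError(
                    f"<p_{j}^2> <= 0 at R={moments.R}, "
                    f"{moments.precision_digits} digits: precision exhausted")
            s1 = _dot_moments([mpf(0)] + sq, M)
            aj = s1 / s0
            a.append(aj)
            norms.append(s0)
            polys.append(list(p_cur))
            if j > 0:
                b.append(s0 / s0_prev)
            s0_prev = s0
            # p_{j+1} = x p_j - a_j p_j - b_j p_{j-1}
            p_next = [mpf(0)] + list(p_cur)
            for i, c in enumerate(p_cur):
                p_next[i] -= aj * c
            if j > 0:
                for i, c in enumerate(p_prev):
                    p_next[i] -= b[-1] * c
            p_prev, p_cur = p_cur, p_next
    return RecurrenceCoefficients(moments.R, N, a, b, norms, polys,
                                  moments.precision_digits)


# ---------------------------------------------------------------------------
# quadrature rule
# ---------------------------------------------------------------------------

@dataclass
class QuadratureRule:
    """N-point rule for int_0^inf f(x) W(R, x) dx ~ sum_a f(x_a) w_a."""

    R: float
    N: int
    points: np.ndarray
    weights: np.ndarray


def _p_and_deriv(x, a, b, N):
    """Monic p_N(x) and p_N'(x) by the three-term recurrence."""
    p_m1, p = mpf(0), mpf(1)
    d_m1, d = mpf(0), mpf(0)
    for j in range(N):
        bj = b[j - 1] if j > 0 else mpf(0)
        p_n = (x - a[j]) * p - bj * p_m1
        d_n = p + (x - a[j]) * d - bj * d_m1
        p_m1, p, d_m1, d = p, p_n, d, d_n
    return p, d


def _christoffel_weight(x, rc: RecurrenceCoefficients):
    """w(x) = 1 / sum_{j<N} p_j(x)^2 / <p_j^2>  (== v_{0}^2 erf(R))."""
    s = mpf(0)
    p_m1, p = mpf(0), mpf(1)
    for j in range(rc.N):
        s += p * p / rc.sq_norms[j]
        bj = rc.b[j - 1] if j > 0 else mpf(0)
        p_m1, p = p, (x - rc.a[j]) * p - bj * p_m1
    return 1 / s


def _rule_from_coefficients(rc: RecurrenceCoefficients) -> QuadratureRule:
    N = rc.N
    with mp.workdps(rc.precision_digits):
        a_f = np.array([float(v) for v in rc.a])
        b_f = np.sqrt(np.array([float(v) for v in rc.b])) if N > 1 else np.empty(0)
        try:
            seeds = eigh_tridiagonal(a_f, b_f, eigvals_only=True)
        except Exception as exc:  # pragma: no cover - degenerate input
            raise PrecisionExhaustedError(
                f"double-precision eigenvalue seeding failed: {exc}") from exc
        tol = mpf(10) ** (-(rc.precision_digits - 8))
        pts = []
        for seed in seeds:
            x = mpf(float(seed))
            for _ in range(100):
                p, d = _p_and_deriv(x, rc.a, rc.b, N)
                if d == 0:
                    raise PrecisionExhaustedError("Newton derivative vanished")
                dx = p / d
                x -= dx
                if abs(dx) <= tol * max(abs(x), mpf(1)):
                    break
            else:
                raise PrecisionExhaustedError("Newton refinement stalled")
            pts.append(x)
        pts.sort()
        if any(p2 <= p1 for p1, p2 in zip(pts, pts[1:])) or pts[0] <= 0:
            raise PrecisionExhaustedError(
                "quadrature points not strictly increasing and positive")
        wts = [_christoffel_weight(x, rc) for x in pts]
    points = np.array([float(x) for x in pts])
    weights = np.array([float(w) for w in wts])
    if np.any(weights < -1e-30):
        raise RuntimeError("negative quadrature weight: eigen failure")
    return QuadratureRule(rc.R, N, points, weights)


def _conditioning_digits(R: float, N: int) -> int:
    """Decimal digits lost by the monomial-basis inner products at radius R."""
    return int(math.ceil(2 * N * math.log10(max(R, math.e))))


def build_gdq(R: float, N: int,
              precision_digits: int = DEFAULT_PRECISION_DIGITS) -> QuadratureRule:
    """Build the N-point GDQ rule at radius R, downcast to machine precision.

    Working precision starts at ``precision_digits`` plus an a-priori
    conditioning allowance of ceil(2N log10 R) digits, and doubles (capped)
    on :class:`PrecisionExhaustedError`.
    """
    if R <= 0:
        raise ValueError("build_gdq requires R > 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    digits = precision_digits + _conditioning_digits(R, N)
    cap = max(MAX_PRECISION_DIGITS, 2 * digits)
    while True:
        try:
            mt = moment_table(R, 2 * N, digits)
            rc = recurrence_coefficients(mt, N)
            return _rule_from_coefficients(rc)
        except PrecisionExhaustedError:
            if digits >= cap:
                raise
            digits = min(2 * digits, cap)


# ---------------------------------------------------------------------------
# per-grid cache
# ---------------------------------------------------------------------------

_RULE_CACHE: dict = {}
_RULE_CACHE_MAX = 4096


def _cache_key(R: float, N: int) -> tuple:
    # R rounded to 15 significant digits keys grid points robustly
    return (f"{float(R):.15g}", int(N))


def cached_gdq(R: float, N: int,
               precision_digits: int = DEFAULT_PRECISION_DIGITS) -> QuadratureRule:
    """Memoized :func:`build_gdq`; rules are reused across matrix assemblies."""
    key = _cache_key(R, N)
    rule = _RULE_CACHE.get(key)
    if rule is None:
        rule = build_gdq(R, N, precision_digits)
        if len(_RULE_CACHE) >= _RULE_CACHE_MAX:
            _RULE_CACHE.clear()
        _RULE_CACHE[key] = rule
    return rule


def clear_rule_cache() -> None:
    _RULE_CACHE.clear()


# ---------------------------------------------------------------------------
# structured-text cache files
# ---------------------------------------------------------------------------

def save_rules(path, rules: Sequence[QuadratureRule]) -> None:
    """Write rules as a JSON array with 17-significant-digit decimal strings."""
    records = [
        {
            "R": f"{rule.R:.17g}",
            "N": rule.N,
            "points": [f"{x:.17g}" for x in rule.points],
            "weights": [f"{w:.17g}" for w in rule.weights],
        }
        for rule in rules
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_rules(path) -> list[QuadratureRule]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        QuadratureRule(
            R=float(rec["R"]),
            N=int(rec["N"]),
            points=np.array([float(x) for x in rec["points"]]),
            weights=np.array([float(w) for w in rec["weights"]]),
        )
        for rec in records
    ]
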