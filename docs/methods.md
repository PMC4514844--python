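# Methods

This note documents the model, the numerical choices and their known
limits, in enough detail to judge what a green test does and does not
establish.

## Model and discretization

The package integrates the spherically-symmetric diffusion equation

    ∂c/∂t = (D/r²) ∂/∂r (r² ∂c/∂r) + s(r, t),    c(r, 0) = c₀,

with a point source s = χ(t) j(t) δ(r)/4πr² whose gate χ ∈ {0, 1} and flux
j are piecewise constant on intervals of length Δt. Over one interval the
solution splits exactly into (i) the new-particle source profile, the
textbook erfc solution of a constant point source, and (ii) the free
propagation of the existing profile by the heat kernel. After
nondimensionalizing r by the diffusion length 2√(DΔt) and substituting
ρ(R) = R·c(r), the 3-D propagation convolution collapses to a 1-D integral
against the kernel

    W(R, R′) = π^{-1/2}[e^{-(R-R′)²} − e^{-(R+R′)²}]
             = (2/√π) e^{-R²-R′²} sinh(2RR′),

and one step is ρₙ₊₁(R) = ∫₀^∞ ρₙ W(R,·) dR′ + χₙFₙ erfc(R) with the flux
factor Fₙ = jₙ/(8πD^{3/2}Δt^{1/2}) (denominator 4π→2π for a half-space
source on a membrane; `geometry_factor`). Because the step is exact in Δt,
stability is unconditional: Δt is chosen to resolve the *source gating*,
not the diffusion operator. The kernel switches to the sinh form when
2RR′ < 10⁻⁴, where the difference of Gaussians cancels catastrophically.

The profile value at the origin is ρ(0) = χₙFₙ: W(0,·) ≡ 0 kills the
propagation row and erfc(0) = 1 carries the source, which is the correct
limit of R·c since c diverges like j/(4πDr) at an active point source.
No pinning of ρ(0) is applied; `to_physical` reports c(0) as the linearly
extrapolated limit of ρ/R from the two innermost nonzero grid points.

## Gauss-diffusion quadrature

Per grid radius R the N-point rule for weight function W(R,·) on (0,∞) is
built from moments Mₙ = ∫ xⁿ W(R,x) dx. Seeds M₀ = erf R, M₁ = R,
M₂ = (R²+½)erf R + R e^{-R²}/√π, M₃ = R(2R²+3)/2 and the parity-split
recurrences (from the contiguous relation of the confluent hypergeometric
function Φ(a, 3/2; R²))

    M₂ₖ   = (R² + 2k − 3/2) M₂ₖ₋₂ + (k−1)(3/2−k) M₂ₖ₋₄,      k ≥ 2,
    M₂ₗ₊₁ = (R² + 2l − 1/2) M₂ₗ₋₁ − (l−1/2)(l−1) M₂ₗ₋₃,      l ≥ 2.

Monic orthogonal polynomials follow from aⱼ = ⟨xpⱼ²⟩/⟨pⱼ²⟩ and
bⱼ = ⟨pⱼ²⟩/⟨pⱼ₋₁²⟩, with inner products formed by convolving coefficient
lists and dotting with the moment vector. This map is the ill-conditioned
part: coefficients of pⱼ grow like R^j and the inner products cancel down
to O(1), losing ≈ 2N·log₁₀R decimal digits. All of it therefore runs in
mpmath arbitrary precision with a working precision of

    digits = precision_digits (default 120) + ⌈2N·log₁₀(max(R, e))⌉,

doubling (capped at max(480, 2× the initial value)) whenever a squared
norm comes out non-positive ("precision exhausted"). The a-priori
allowance matters: a flat 120 digits fails for every rule with R ≈ 5000 at
N = 20.

Points are the eigenvalues of the symmetric tridiagonal Jacobi matrix
(diagonal aⱼ, off-diagonal √bⱼ), equivalently the roots of p_N; they are
found by Newton refinement of double-precision `eigh_tridiagonal` seeds,
evaluated through the three-term recurrence at working precision
(quadratic convergence, ~4 iterations, with monotonicity/positivity checks
as a safeguard). Weights use the Christoffel identity
w_α = 1/Σⱼ pⱼ(x_α)²/⟨pⱼ²⟩, algebraically equal to the squared first
eigenvector component times erf R but requiring no eigenvectors. Finished
rules are downcast to float64 and memoized per (R to 15 significant
digits, N); the downcast sacrifices nothing, as the 100→150 digit
invariance test shows. Rules serialize to JSON with 17-significant-digit
decimal strings.

## Interpolation grid

The exact profile after any gating history is ρₙ = Σₘ χₙ₋ₘFₙ₋ₘ eₘ(R) with
e₀ = erfc R, eₘ = erf(R/√m) − erf(R/√(m+1)), so the grid is designed to
interpolate the eₘ family well. The domain [0, R_max] splits at R = 10:
the near interval (where e₁ has essentially all of its structure) is
seeded with `near_base` linearly spaced points, the far interval with
`far_base` points uniform in log R; grid size therefore grows only
logarithmically with the simulation horizon. With a finite tolerance each
subinterval is bisected until the 4-point (cubic) interpolant of every
swept eₘ matches the midpoint value within tol, for
m ∈ {0..20, 30, 50, 100, 200, 500} — large m add almost nothing, so
sparse sampling suffices; the loop repeats until the certificate holds for
all m simultaneously on the final grid (depth capped at 40). With
tol = ∞ ("prescribed-counts" mode, used by the parameter sweep and all
fixed-configuration runs) the seeds are used as-is.

R_max comes from the worst-case always-on criterion
F_max·erfc(R/√n_steps) = ε·R solved by bracketed bisection; n_steps = 1
recovers the single-step form. The worked example's R_max = 5148 is
treated as a given input: the printed threshold ε = 10⁻¹⁷ does not
reproduce it under any unit reading we tried, so reproductions use the
domain, not the solver.

## Stencils and matrix assembly

Interpolation weights at a quadrature point come from the standard
function-value (derivative order 0) Fornberg recursion over the N_F
stencil nodes only, validated against direct Lagrange evaluation.
Stencils are contiguous windows of the N_F grid nodes nearest the target;
distance ties extend toward larger R (profiles decay outward). One
amendment to pure nearest-selection proved necessary: when the target
falls inside a locally coarse interval (the first gap past the near/far
spacing change of a prescribed-counts grid), the nearest window puts
N_F − 1 nodes on the fine side, and that one-sided high-degree stencil
oscillates — the spectral radius of W then reaches 4–800 and long runs
diverge, the same large-N_F divergence mode the error harness is designed
to catch. Enforcing a minimum of min(3, ⌊N_F/2⌋) nodes per side of the
target (where the grid allows) restores a balanced stencil exactly in
those gaps, is a no-op wherever spacing is locally smooth, and was fixed
once by spectral-radius analysis of the studied configurations, not by
error tuning. High interpolation orders (N_F ≳ 10 on dense near grids)
still diverge, as they should.

Row i of W accumulates A_j(x_α(R_i))·w_α(R_i) over the rule at R_i; row 0
is empty. Quadrature points beyond R_max (at most R_max + ~4.5) use the
boundary-clamped stencil — the profile there is ≈ 0 by construction of
R_max — and a warning fires if they overshoot by more than 10%. Entries
below 10⁻¹⁶ of their row maximum are dropped (denormal noise otherwise
inflates the nonzero count, which is the method's per-step cost measure).
The matrix is stored sparse (CSR) with a dense copy for fast stepping of
these small systems; at the optimal working point (I = 115, N = 10,
N_F = 8) it has 1363 nonzeros.

## Reaction extension

In the high-buffer limit (free buffer b and bound buffer B constant) the
equation gains −k₊bc + k₋B. The binding sink uses a one-point time
quadrature at tₙ, multiplying the propagated profile by (1 − k₊bΔt),
which requires k₊bΔt < 1; the unbinding source adds a uniform
concentration k₋BΔt per step — the heat kernel integrates to exactly 1
over ℝ³, so its nondimensional form is k₋BΔt·R with unit prefactor. A
`buffer_source_multiplier` (default 1) exposes alternative prefactor
conventions for comparison. The scheme's uniform fixed point is exactly
c_eq = k₋B/(k₊b), and its one-step error against the exponential
relaxation is O(Δt²), verified by Δt-halving.

## Error harness and its meaning

εsim(t) = (1/F)·max_R |ρ_sim − ρ_exact| at the grid radii; with this
scaling the exact result is flux- and D-independent, so all validation
runs are dimensionless with F = 1, and −log₁₀ εsim approximates the
number of correct significant digits of ρ/F. Always-on runs compare
against erfc(R/√k) at every step over arbitrary horizons. Random-on runs
(seeded Bernoulli gate, p_on = 0.5 unless configured) compare against the
exact history sum, whose per-evaluation cost is O(n·I); eₘ columns are
precomputed once per grid and comparisons run at a fixed cadence (default
every 250 steps plus the final step) to keep the total O(n²) tractable.
Divergence is declared at |ρ|/F > 10¹⁰ and reported, not raised, by the
harness. The parameter sweep reports εsim (truncated at 1) against nnz,
flags the Pareto frontier, and selects the minimal-nnz set meeting a
target. The Crank–Nicolson baseline solves v_t = D v_rr for v ∝ r·c on a
uniform grid with the source as inner boundary value v(0) = χ — its
source discretization is our choice, so it supports qualitative
comparison and self-convergence checks only.

What the harness establishes: with validated parameters the stepped
solution tracks the closed forms for ≥ 10⁶ steps with no secular error
growth, and across the six studied grid-resolution cases the random-on
error maximum stays below the always-on maximum (three seeds), so the
cheap always-on test bounds the error of production runs with arbitrary
gating. What it does not establish: accuracy for smoothly-varying fluxes
between gate switches (piecewise-constant j is assumed), for multiple
spatially separated sources, or for buffers that deplete.

## Known limitations

* The startup transient of coarse near grids is real: at the optimal
  working point the one-application interpolation error of erfc near the
  origin makes εsim peak at 3.7×10⁻⁵ on steps 2–4 before settling to
  ~1.6×10⁻⁷. Error budgets that must include the first few steps need
  either more near points or a larger N_F (at proportionally more
  nonzeros).
* Prescribed-counts grids inherit an abrupt spacing change at R = 10; the
  stencil side-guard handles it, but refined grids (finite tol) are the
  better-conditioned choice when exact point counts are not required.
* The random-on oracle's O(n²) total cost caps practical comparison
  horizons near ~5×10⁵ steps; the always-on bound covers longer runs.
* c(0) is reported as a two-point extrapolated limit; while the source is
  on, the physical concentration at r = 0 is infinite and the extrapolated
  value is a near-field summary, not a pointwise concentration.
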