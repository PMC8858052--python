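# Methods

## Model

Five compartments of a treated breast-cancer cohort — stages 1–2 pooled
(C_A), stage 3 (C_B), stage 4 (C_C), disease-free (C_D), cardiotoxic
(C_E) — coupled by an affine vector field dC/dt = A C + b. The matrix A is
Metzler (all off-diagonal entries are transition rates, hence ≥ 0) and
b = (η₁, η₂, η₃, 0, 0) ≥ 0, so the classical flow preserves the nonnegative
orthant. Column sums of A are (0, −γ₂, −γ₃, 0, −γ₁): each internal transfer
appears once as a gain and once as a loss, so total population changes only
through recruitment and the three death rates — an identity the tests check
to machine precision.

Modelling assumptions worth stating explicitly: all flows are first-order
(no saturation, no logistic tumour growth), rates are time-invariant (no
treatment scheduling), the cardiotoxic state absorbs from B, C and D, and
recruitment is constant. Parameter estimation from patient data is out of
scope; the model is a mechanism for exploring rate and memory effects, not
a fitted description of a cohort.

## Fractional formulation

The fractional variant replaces d/dt with the Caputo–Fabrizio derivative of
order ϑ ∈ (0, 1],

D^ϑ h(t) = 1/(1−ϑ) ∫₀ᵗ h′(x) e^{−ϑ(t−x)/(1−ϑ)} dx,

with exponential (nonsingular) kernel. The kernel exponent is taken
*decaying*; one printed variant of the definition omits the minus sign, but
only the decaying kernel yields bounded operators and the inversion
property, so it is used throughout. The normalization U(ϑ) = 2/(2−ϑ) makes
the CF integral the convex combination I^ϑ f(t) = c₁ f(t) + c₂ ∫₀ᵗ f with
(c₁, c₂) = (1−ϑ, ϑ); the unsimplified coefficient forms
2(1−ϑ)/((2−ϑ)U(ϑ)) and 2ϑ/((2−ϑ)U(ϑ)) are kept in `cf_coefficients` and a
test proves they equal (1−ϑ, ϑ) and sum to 1. (The CF literature also
asserts U(0) = U(1) = 1, which contradicts U(ϑ) = 2/(2−ϑ) at ϑ = 1; we
follow the derived 2/(2−ϑ) and do not attempt to reconcile the two.)

Applying I^ϑ to D^ϑ C = f(C) gives the Volterra form

C(t) = C₀ + c₁ [f(C(t)) − f(C₀)] + c₂ ∫₀ᵗ f(C(s)) ds.

The subtraction of f(C₀) is essential: without it the right-hand side at
t = 0 equals C₀ + c₁ f(C₀) ≠ C₀, i.e. the representation would contradict
the initial condition. The correction cancels identically when the
equation is differenced between consecutive time nodes, so it appears
explicitly only in the Picard iteration and the exact oracle.

### Operator numerics

Both operators act on uniformly sampled functions and use composite
trapezoid quadrature. For the derivative, h′ comes from centered
differences (second-order one-sided stencils at the ends), and the kernel
integral over [0, t_m] is accumulated through the exponential kernel's
exact per-step decay factor e^{−ah} (a = ϑ/(1−ϑ)) — an O(N) linear
recurrence (evaluated with `scipy.signal.lfilter`) that reproduces the
composite trapezoid sum at every node without the O(N²) cost and without
overflowing for ϑ near 1. Edge orders: ϑ = 1 dispatches to the plain
derivative/integral; ϑ = 0 (integral only) returns f(t). Accuracy is
verified against closed forms — for h(t) = t,
D^ϑ h(t) = (1/ϑ)(1 − e^{−ϑt/(1−ϑ)}) — and by the inversion property
I^ϑ(D^ϑ h) = h on t, t², t³ (≤ 1e−6 sup error at 10⁴ nodes on [0, 1]).

## Equilibrium

The field is affine, so the unique equilibrium is −A⁻¹b whenever A is
nonsingular; this linear solve is the package's ground truth (residual
below 1e−12·(1+‖b‖∞) enforced). The printed closed-form expansion for the
equilibrium (scalars α, β, ξ, v, λ over denominators k₁λ, k₁λγ₁) is typeset
without grouping symbols and contains at least one evident typo (a bare
"η"); `equilibrium_closed_form` therefore implements one documented literal
reading, always cross-checks it against the linear solve, and attaches a
`TranscriptionWarning` with per-component relative errors when they
disagree (they do, on generic parameters). The first component
C_A* = η₁/(δ_AD + δ_AB) follows from the decoupled first equation and is
exact in both routes. Eigenvalues of A are reported as a supplementary
stability diagnostic; they are not part of the fixed-point analysis.

## Existence and uniqueness checks

The five Volterra kernels are affine, so their exact Lipschitz constants in
their own state are the self-coupling magnitudes: μ₁ = δ_AD + δ_AB,
μ₂ = k₂, μ₃ = k₃, μ₄ = δ_DB + δ_DC + δ_DE, μ₅ = γ₁ (μ₂–μ₅ are not spelled
out in the source; a numerical Lipschitz estimate over random state pairs
confirms them). The contraction analysis is driven by μ₁: kernels are
contractions iff μ₁ < 1; the guaranteed-existence horizon is
t₀ = (1 − c₁μ₁)/(c₂μ₁) (infinite when μ₁ = 0, zero when c₁μ₁ ≥ 1); and
uniqueness requires 1 − c₁μ₁ − c₂μ₁ t > 0, which flips exactly at t₀.
Parameters are deliberately *not* constrained to μ₁ < 1 at construction —
the condition is a diagnostic of the proof technique, not a validity bound
of the ODE.

The scalar per-iteration contraction bound c₁μ₁ + c₂μ₁T applies rigorously
to the C_A component of the Picard iteration (its kernel is autonomous).
The coupled five-component iteration in sup norm contracts more slowly than
the scalar bound suggests (off-diagonal couplings enter); it still
converges inside the horizon, which is how the tests phrase the check.

## Solvers

**CF two-step Adams–Bashforth (default).** Differencing the Volterra form
between nodes gives Δy_n = c₁[f(y_{n+1}) − f(y_n)] + c₂∫ over the step; the
integral is extrapolated with the classical two-point Adams–Bashforth rule
c₂h(3f_n − f_{n−1})/2. For the increment term two treatments are provided.
The default resolves it exactly — the field is affine, so
(I − c₁A) Δy_n = c₂h(3f_n − f_{n−1})/2 costs one 5×5 inverse per run — and
is second-order accurate for every ϑ (verified by step-halving against the
oracle). The fully explicit variant (`increment="lagged"`) replaces the
increment by the lagged difference c₁(f_n − f_{n−1}), the linear-
extrapolation estimate of f(y_{n+1}) − f(y_n); it is first-order for ϑ < 1
and is kept as a scheme-sensitivity diagnostic. Both bootstrap the missing
first node with the Euler step of the integral term, y₁ = y₀ + c₂h f₀
(resolved through (I − c₁A) in the default); a bootstrap that adds the full
c₁ f₀ increment was rejected because it imprints a spurious O(c₁f₀) jump —
it solves the uncorrected Volterra equation, whose effective initial value
differs from y₀. At ϑ = 1 (c₁ = 0, c₂ = 1) both variants take the identical
code path as the independently written classical AB2, so the reduction is
bitwise. Defaults: h = 0.01, T = 50, both CLI-overridable.

**Exact linear oracle.** Differentiating the Volterra form gives the
equivalent ODE (I − c₁A) y′ = c₂(Ay + b), hence
y(t) = y∞ + e^{Bt}(y₀ − y∞) with B = c₂(I − c₁A)⁻¹A and y∞ = −A⁻¹b.
Evaluation goes through the eigendecomposition of B (vectorised over the
grid), falling back to per-node `scipy.linalg.expm` when the eigenvector
matrix is ill-conditioned (condition number above 1e8). This route shares
no discretisation with the schemes it checks.

**Picard.** Successive substitution into the Volterra form on a fixed grid
with trapezoid quadrature, starting from the constant function y⁽⁰⁾ ≡ y₀,
stopping when the sup norm of successive iterates falls below `tol`
(default 1e−7) or raising with the full delta history at `max_iter`
(default 500). The default tolerance is set just above the method's
floating-point noise floor: the Volterra map is non-normal and its early
iterates overshoot by orders of magnitude before the factorial decay takes
over, which amplifies rounding noise to ~1e−8 on the baseline horizon.
A warning is emitted when the grid extends beyond t₀.

**Classical RK4** integrates the ordinary system as a reference; at ϑ = 1
it agrees with the matrix-exponential solution to ~1e−12 at h = 1e−3.

## Scenarios

Eight sweep presets reproduce the study's simulation design (two
fractional-order triples and six transition-rate triples, values exactly as
printed in the figure captions), plus the classical-vs-fractional
comparison at ϑ = 0.9. Non-swept quantities are held at the baseline
fixture and each result records that choice in its metadata. The
comparison's classical leg defaults to RK4; `classical_scheme="ab2"`
selects classical AB2, which at ϑ = 1 reproduces the fractional leg
bitwise.

The narrative's qualitative claims ("raising δ_BE raises the cardiotoxic
level", etc.) are encoded as expected signs of the equilibrium sensitivity
∂C_i*/∂rate, computed by central finite differences of the linear-solve
equilibrium (relative step 1e−6, clipped at zero since rates are
nonnegative). Mismatches are returned as structured records, never
suppressed: on the baseline fixture one claim disagrees (raising δ_AD
*lowers* the stage-4 equilibrium, because the larger disease-free pool
feeds back through δ_DC more weakly than direct inflow shrinks), and two
of the narrative's statements about δ_BD contradict each other (C_B both
"decreases" and "increases slightly"); the first statement is the one
encoded.

## Baseline fixture

No baseline parameter table is printed in the source study; the shipped
fixture is an assumed configuration, labelled as such in every output.
Swept rates take the middle printed sweep value (δ_AD = 0.0651,
δ_BD = 0.442, δ_BE = 0.631, δ_CD = 0.458, δ_CE = 0.396, δ_DE = 0.422).
The remaining choices are plausible magnitudes for a hospital cohort per
unit time: recruitment η = (5, 3, 2) patients/time, descending with stage
at first presentation; slow direct progression δ_AB = 0.05, δ_BC = 0.1
compared with the treated transitions; small relapse rates
δ_DB = δ_DC = 0.02; death rates γ₁ = 0.1, γ₂ = 0.05, γ₃ = 0.1; initial
cohort (60, 40, 20, 0, 0); ϑ = 0.9, h = 0.01, T = 50. The fixture
satisfies μ₁ = 0.1151 < 1, has nonsingular A and all eigenvalue real parts
negative, so every solver relaxes to the unique equilibrium.

What the fixture does and does not emulate: it exercises realistic
magnitudes, stiffness ratio (fastest/slowest mode ≈ 12) and the contraction
regime of the analysis, so passing tests demonstrate the numerics and the
analysis machinery. It is not calibrated to any clinical cohort, so
simulated levels (e.g. the large cardiotoxic equilibrium) are properties of
the assumed rates, not clinical predictions.

## Numerical choices and problem sizes

Operator tests use 10⁴+1 nodes on [0, 1] (quadrature error ~1e−8, asserted
at 1e−6). Solver cross-checks run on [0, 10] with h down to 1e−3 and four
step-halvings from 1.6e−2; Picard runs on [0, 8] (inside the ϑ = 0.9
horizon t₀ ≈ 9.54) with 1601 nodes. Equilibrium consistency is checked on
1000 random nonnegative parameter draws. Long-run relaxation is asserted at
T = 200: below 1e−6 of the equilibrium at ϑ = 1 and below 2e−6 at ϑ = 0.9 —
the fractional system's slowest mode c₂λ/(1 − c₁λ) is slightly slower than
λ itself, so the classical figure does not carry over verbatim. These sizes
keep the full suite under ten seconds on one CPU while leaving the asserted
tolerances an order of magnitude above observed errors.

## Known limitations

- The equilibrium closed-form transcription is advisory by construction;
  its printed source appears corrupted and no bracketing we tried matches
  the linear solve on generic parameters.
- The lagged explicit AB2 variant is only first-order for ϑ < 1; it exists
  for comparison, not production use.
- Sensitivity signs are equilibrium-based; transient (finite-horizon)
  directions can differ and are only exposed through the sweep terminal
  states.
- No delay terms, controls, nonlinear growth or parameter estimation.
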