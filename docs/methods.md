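# Methods

## Model and assumptions

The converter is a three-step enzymatic cycle — substrate binding,
internal conversion coupled to ATP hydrolysis, product release — whose
state energies are chemical potentials μ₁…μ₄ with activation barriers
h₁…h₃. Mass-action kinetics with Arrhenius rate constants give exact
net step velocities wᵢ = Aᵢ(1 − e^(−αᵢ/RT)) with step affinity
αᵢ = μᵢ − μᵢ₊₁ and amplitude Aᵢ = ξᵢ e^(−hᵢ/RT). The model's
assumptions, in decreasing order of consequence:

1. **Steady state near equilibrium.** All affinities are small against
   RT, so velocities are linear in the forces. No time integration of
   the mass-action ODEs is performed anywhere; the package is a
   steady-state theory.
2. **Amplitude topology A₁ = A₃ = A, A₂ = βA.** This is the only
   coefficient structure supported; it forces a symmetric Onsager
   matrix with L₁₁ = L₂₂ = A(β−1), L₁₂ = A, hence phenomenological
   stoichiometry Z = 1 exactly and degree of coupling q = 1/(β−1).
   Arbitrary (A₁, A₂, A₃) and asymmetric L matrices are out of scope.
3. **Passivity.** β < 2 would give q > 1 and det L < 0, violating the
   Cauchy–Schwarz bound for a passive converter; `build_converter`
   rejects it unless `allow_overcoupling=True` is passed explicitly
   (exploration only).

The two lumped fluxes (J₁, the dissipation-like sum of step
velocities, and J₂) are used exactly as the flux–force construction
defines them; no further physical identification is attempted.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| q | degree of coupling, L₁₂/√(L₁₁L₂₂) | sweep {0.2, 0.4, 0.6, 0.8, 0.95, 1.0} | spans weak to complete coupling; 0.95 is the measured value for oxidative phosphorylation in rat-liver mitochondria, 1.0 the reversible-capable limit |
| x | force ratio X₁/X₂, the operating variable | grid on [−1, 0], 401 points | [−q, 0] is the power-delivering range; 401 points resolve optima to ~2.5e−3 |
| Z | phenomenological stoichiometry | 1 (fixed) | forced by the coefficient construction; only `efficiency()` accepts general Z |
| T, Δ, A | temperature, potential gap μ₁−μ₄, rate amplitude | dimensionless mode (R·T = 1, scale = 1) | all characteristic functions factor as (reduced shape) × T·L₂₂·Δ²; the shape is what the theory is about |
| R | gas constant | 8.314 J K⁻¹ mol⁻¹ | SI; only used in dimensional mode |

Reduced units are the default everywhere. Absolute values are an
explicit multiplication by `DriveConditions.scale` = T·L₂₂·Δ²; the
absolute entropy-production prefactor is scale/T = L₂₂·Δ², chosen so
that the ecological identity E = P − T·σ holds exactly in absolute
units as well as reduced ones. (The power convention P = −T·J₁X₁
carries a factor T; keeping the identity exact fixes the σ prefactor
uniquely.)

## Numerical choices

* **η-parameterized curves are computed by composition, never by a
  transcribed η-domain formula.** The x-domain forms are simple
  polynomials/rationals; the inversion x(η) is the quadratic
  x² + q(1+η)x + η = 0 with discriminant (1+η)² − 4η/q² (in the scaled
  form). Branch labels: "upper" = root of smaller |x|, "lower" =
  larger; loops concatenate lower (η ascending) then upper
  (η descending).
* **The q = 1 degeneracy.** At complete coupling the inversion
  quadratic factors as (x+1)(x+η): the x = −1 root is the efficiency
  pole (the reversible point) introduced by clearing the denominator,
  not a genuine operating point. `x_from_eta` returns both roots as
  the algebra produces them; `loop_curve` places both branches on the
  physical root x = −η at q = 1, so the loop degenerates to the
  single-valued curve with zero shoelace area. Round-trip guarantees
  (η → x → η to 1e−10) therefore apply to q < 1 and to the upper
  branch at q = 1.
* **Removable singularity.** Efficient power x²(x+q)²/(qx+1) has its
  pole at x = −1/q; at q = 1 the pole coincides with a zero of the
  numerator and the function is evaluated in the cancelled form
  x²(x+1).
* **MEPF optimum.** The printed closed form for the
  maximum-efficient-power efficiency is unreliable; the implementation
  solves the stationarity quadratic 3qx² + (4+q²)x + 2q = 0 (the
  numerator of d pe/dx after dropping the flux factor x(x+q), verified
  symbolically in the test suite) and takes the root interior to
  (−q, 0). An independent algebraic reconstruction
  (`eta_mepf_closed_form`) is shipped and asserted to agree on the
  whole q grid; a discrepancy fails the suite rather than being
  silently reconciled.
* **Numeric oracle.** `numeric_argmax` is scipy's bounded Brent
  minimization (xatol 1e−10) of the negated reduced function over
  (−q, 0), widened to (−1, 0) for the ecological function. There is no
  randomness anywhere in the package; results are deterministic.
* **Precision limits.** Near a smooth maximum the argmax is determined
  only to ~√(machine ε); the analytic/numeric residual gate is 1e−8 on
  the efficiency, which the Brent parabola fits comfortably meet
  (observed residuals ≤ 4e−9).
* **Small affinities.** The exact net velocity uses `expm1`; a naive
  1 − e^(−ε) loses enough precision at ε ≈ 1e−6 to break the
  Taylor-remainder bound ε/2·(1+ε) through round-off alone.
* **Grids.** Default x grid 401 points on [−1, 0]; loop curves 201
  η points per branch on [0, η_max(q)]; explicit η grids exceeding
  η_max are clipped with a logged warning, and grid samples on the
  efficiency pole are flagged NaN rather than dropped.

## Design choices where the design was open

* **Regime ordering.** η\*(MPO) ≤ η\*(MEPF) ≤ η\*(MEF) holds near
  complete coupling (½ ≤ ⅔ ≤ ¾ at q = 1) but is **not** a global law:
  the MPO and MEF efficiencies cross at q = √(2/3) ≈ 0.8165, and for
  weaker coupling the ecological optimum x\* = −3q/4 lies past the
  efficiency peak so η\*(MEF) ~ 3q²/16 < η\*(MPO) ~ q²/4. The tests
  assert the ordering on q ∈ [0.9, 1], verify the crossing point, and
  verify the inversion at small q.
* **Entropy-production monotonicity.** σ(x) = x² + 2qx + 1 is a
  parabola with minimum at x = −q, not a monotone function of x; the
  package exposes it as derived from the dissipation identity
  T·σ̃-form = J₁X₁ + J₂X₂ and makes no monotonicity claim. What is
  true, and tested, is that at fixed x the dissipation falls as the
  coupling rises.
* **CLI and config.** The tool surface is three subcommands (`sweep`,
  `optimum`, `loop`) over the library; a flat TOML file can pre-set
  grid options and explicit flags override it; every run logs the
  resolved configuration and a short hash of it into the output
  metadata. Plotting is a convenience flag; tabular output is the
  contract.

## What the tests do and do not show

Inputs are scalar model parameters, so there is no synthetic-data
generator emulating measurement noise: the test fixtures are the
analytic structure itself (landmark rationals at q = 1, identities
E = P − σ and Pe = η·P, round trips, and closed-form/oracle
agreement on a 20-point q grid at 1e−8). Passing tests show the
implementation realizes the linear theory exactly; they say nothing
about how well a real enzyme system satisfies the linearity,
topology-of-amplitudes, or steady-state assumptions — at affinities of
order RT the linearized velocities already deviate by ~50% of the
affinity, as the linearization tests quantify.

## Known limitations

* Only the symmetric coefficient topology (Z = 1); no fitting of q, A
  or β to experimental flux data.
* No time-dependent behaviour, no minimum-entropy-production or
  omega-function regimes, no thermal-reservoir (Carnot-type) engines.
* The loop curves are exact parameterizations, not reconstructions
  from noisy sweeps; their areas are grid-resolution limited.
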