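# Methods

## The problem

`fracspectral` solves initial-value problems for systems of Caputo
fractional ODEs,

    D^(eta_i) y_i(t) = f_i(t, y(t)),   y(0) = y0,   0 < eta_i <= 1,

on a horizon [0, k], by spectral residual minimization.  The bundled
application is a five-compartment breast-tissue competition model (cancer
stem cells C, tumor cells T, healthy cells H, immune cells I, excess
estrogen E) with logistic growth, immune predation, estrogen-driven
proliferation and mutation, a constant immune source s and continuous
estrogen infusion tau.  Replacing d/dt by the Caputo derivative introduces
memory; dimensional consistency requires every day^-1 rate in equation i to
be raised to the power eta_i (so it carries day^-eta_i), which reduces to
the classical model exactly at eta_i = 1.

A consequence worth stating explicitly: raising *small* interaction rates to
fractional powers inflates them enormously (e.g. delta = 6e-8 day^-1 becomes
delta^0.2 ~ 0.04, so the healthy-cell kill term delta^0.2 * H * T is ~1e12
cells/day^0.2 at the benchmark initial state).  At strongly fractional
orders the model therefore develops quasi-instantaneous boundary layers
(healthy cells collapse on a ~1e-27 day timescale); this is a property of
the dimension-corrected model, not a numerical artifact.  It is why the
explicit predictor-corrector oracle diverges there, why the objective
integrand needs a graded quadrature, and why tunable basis exponents (which
can approach t^1e-6, i.e. near-jump behavior) are the right tool.

## The basis

Shifted Legendre polynomials L_j on [0, 1] are generalized by replacing each
monomial t^j (j >= 1) with t^(j + alpha_j), keeping the triangular integer
coefficient table q_kj = (-1)^(k+j) (k+j)! / ((k-j)! (j!)^2).  The
"control parameters" alpha_j are free, per-component exponent shifts subject
only to j + alpha_j > 0 (enforced as >= 1e-6 in the optimizer); alpha = 0
recovers the classical basis.  This is a Müntz-type family: it is not
orthogonal, but its span is dense in C[0,1] and, crucially, it contains
algebraic boundary-layer behavior t^gamma with small gamma that no fixed
polynomial basis of comparable size can represent.

The Caputo derivative acts diagonally on the monomial vector:
D^eta t^p = Gamma(p+1)/Gamma(p+1-eta) t^(p-eta) and D^eta 1 = 0, giving an
exact operational matrix.  Combined exponents p - eta are formed
analytically before evaluation, so t = 0 never produces 0^-eta.

Numerical notes: coefficient tables are built in exact integer arithmetic
and cached; polynomial evaluation accumulates in 80-bit precision because
the monomial form of L_j is badly conditioned (alternating coefficients
~ (2j)!/(j!)^2) — this keeps j <= 15 accurate to below 1e-9.

## The solve

Each component is expanded as y_i = c_i^T Q_i Psi_i(t).  The residuals
R_i(t) = [exact Caputo derivative of the expansion] - f_i(t, y(t)) are
squared, summed and integrated over [0, k] to form the objective M, which is
minimized subject to the initial-condition constraints y_i(0) = y0_i.

* **Scaling.**  The model's states span five orders of magnitude, so
  residual i is divided by a fixed scale s_i — the carrying capacities
  (M1, M2, M3) for C, T, H, the immune threshold omega for I and the
  estrogen threshold v for E.  This equals solving for the nondimensional
  states y_i/s_i.  The reported objective is the scaled one; scaling can be
  turned off.
* **Constraint elimination.**  Psi_i(0) = (1, 0, ..., 0) and Q_i[0,0] = 1,
  so each constraint is linear in the leading coefficient and is eliminated
  exactly; the constraints hold to machine precision by construction.
  Lagrange multipliers are recovered a posteriori from stationarity
  (lambda_i = -dM/dc_i0), and the full Lagrangian gradient (coefficients,
  exponents, multipliers) is exposed for verification.
* **Optimization.**  The reduced problem is a nonlinear least-squares
  problem in the free coefficients and exponents.  Each start runs
  trust-region-reflective (with exponent bounds) followed by an unbounded
  Levenberg-Marquardt polish (accepted only if the exponents remain
  admissible).  Jacobians are complex-step (exact to machine precision; the
  entire evaluation path is complex-safe).  Multistart combines (i) the
  fractional Taylor ladder alpha_j = j(eta_i - 1), (ii) zero shifts,
  (iii) one boundary-layer exponent, (iv) an optional warm start embedded
  exactly from a smaller-basis solution (triangular re-solve), and
  (v) seeded random exponent layouts; coefficients are initialized by a
  linear constrained fit to a predictor-corrector reference trajectory when
  one exists, else to the constant initial state.
* **Quadrature.**  Gauss-Legendre graded by the substitution t = k u^2
  (nodes clustered at 0), with the node count doubled — re-optimizing from
  the incumbent — until the objective changes by < 1e-3 relative.  Without
  grading the boundary-layer residual at strongly fractional orders hides
  mass between nodes and the refinement loop does not converge by 256 nodes.
* **Determinism.**  All randomness flows from one seed; repeated runs give
  identical solutions.
* **Precision.**  Double precision throughout; an mpmath re-evaluation of
  the final objective at configurable digits is available as a diagnostic.
  Empirically the double-precision optimizer resolves objectives down to
  ~1e-14 before evaluation noise matters.

Tunable defaults: horizon k = 1 day (the basis interval), 64 initial
quadrature nodes (cap 256), 6 starts, exponent floor j + alpha_j >= 1e-6,
exponent ceiling alpha_j <= 25.

## The oracles

* `fraccalc.caputo_monomial` — the closed-form power rule, extended to real
  p > 0.
* `fraccalc.caputo_quadrature` — the defining convolution integral.  The
  substitution u = (t - xi)^(1-eta) removes the kernel singularity at xi = t
  analytically; the remaining integrand (singular at xi = 0 when f' blows up
  there) is integrated by a double-exponential rule in 30-digit arithmetic.
  Both pieces are necessary: tanh-sinh alone fails for eta near 1 (the
  kernel tail mass decays like u^(1-eta) and would need ~100 digits), and
  plain Gauss rules fail on the xi = 0 singularity.
* `oracle.pece_solve` — the fractional Adams-Bashforth-Moulton
  predictor-corrector on a uniform grid, one convolution history per
  component (each with its own order), one corrector pass by default.
  Accuracy O(h^(1+eta)); reduces to rectangle/trapezoid Adams at eta = 1.
  It shares no code with the spectral path, making agreement between the two
  a genuine dual-method check.
* `oracle.manufactured_system` — D^eta y = Gamma(p+1)/Gamma(p+1-eta)
  t^(p-eta), y(0) = 0, exact solution t^p, for exact-error measurement.

## What the checks do and do not establish

The test suite verifies: exact basis algebra; agreement of the two Caputo
routes to 1e-6 over a grid including singular integrands; classical-limit
agreement of the spectral solve with adaptive RK to well under 1%;
exact recovery (1e-8) of manufactured power solutions; spectral-vs-PECE
agreement at near-classical orders to 5%; non-increase of the optimal
objective under nested basis refinement; and end-to-end determinism.

No external data are involved anywhere — the model and all benchmark
configurations are fully specified by printed constants, so a green suite
establishes internal and cross-method consistency, not agreement with
biological measurements.  Two published claims are *not* reproduced by the
computation and are deliberately left as failing acceptance checks, with the
quantitative analysis in VALIDATION.md: the published optimal objective
magnitudes (which presuppose an unstated normalization) and the published
qualitative trend summary (structurally impossible from the printed initial
state at near-classical orders).

## Known limitations

* The PECE oracle cannot integrate the strongly fractional benchmark orders
  (genuine model stiffness, see above); cross-validation there rests on
  residual smallness and basis-refinement convergence instead.
* Exponent optimization is non-convex; multistart gives reproducible, not
  certified-global, optima.
* The convergence theory behind the basis assumes strictly increasing
  exponent sequences; the implementation only enforces j + alpha_j > 0 and
  in practice optimized exponents occasionally cross.  This affects the
  interpolation-theoretic guarantees, not the computed residuals.
* Orders are restricted to (0, 1]; no Riemann-Liouville or distributed-order
  variants.
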