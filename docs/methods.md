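# Methods

## Model

The simulator integrates four coupled reaction–diffusion equations for
living yeast-cell density `n`, two dead-cell densities (`m1` accidental,
`m2` regulated), and nutrient `g`, in dimensionless form (see README for the
equations). The modelling assumptions:

- Growth is nutrient-limited and local (`n g`), consuming nutrient at rate
  `C n g`. Mechanics and the extracellular matrix are neglected.
- Living cells spread by degenerate nonlinear diffusion (flux `D_n n ∇n`):
  the effective diffusivity vanishes with the density, giving compactly
  supported colonies with sharp edges, and is the mechanism behind the
  transverse (floral) front instability. A linear-diffusion variant is
  available (`cell_diffusion="linear"`) as the stability control.
- ACD converts living cells to `m1` at rate `Λ1 n (g† − g)` below the
  survival threshold `g†`; RCD converts to `m2` at rate
  `Λ2 n (g − g1)(g2 − g)` inside the window `(g1, g2)`. Both window factors
  vanish at their thresholds, so the rates are continuous and the Heaviside
  convention at exactly the threshold is unobservable; the code uses
  `H(0) = 0` (strict inequalities) for determinism.
- Dead cells break down at first-order rates `Γi`, returning `Ki` units of
  nutrient per broken-down cell. Dead-cell transport is linear Fickian
  diffusion with small coefficients (`D_mi = 0.001` by default): dead cells
  essentially stay where they died, which is what makes them a spatial
  record of where each death mechanism acted.

Summing the equations shows that `∫ C(n + m1 + m2) + g` changes only
through breakdown, at rate `(Ki − C) Γi ∫ mi`; it is exactly conserved when
`Γ1 = Γ2 = 0` (and separately when `Ki = C`). This is the scheme's main
correctness anchor.

## Parameters

All simulations use the thirteen dimensionless groups; dimensional inputs
are converted once via the scaling map (densities by `N0`, nutrient by `G0`,
space by `sqrt(D_g*/(α* G0*))`, time by `1/(α* G0*)`). Defaults shared by
every scenario: `D_n = 0.47` (close to the most-unstable regime of the
death-free model), `D_m1 = D_m2 = 0.001`, `C = 1`, `g† = 0.25`, `g1 = 0`,
`g2 = 1`. The regimes differ in death/breakdown/release settings; see
`yeastcolony list-scenarios`. The biophysical bound `Ki < 10` follows from a
eukaryotic cell mass ~1e-10 (mass units) with `N0 ~ 1e6`, `G0 ~ 1e-5`.

## Discretisation

- Uniform mesh, second-order centred Laplacian. All boundary faces impose a
  vanishing normal derivative — the Petri-dish no-flux wall and the symmetry
  plane at `x = 0` (and `y = 0` symmetry exploited implicitly by the even
  initial data) are the same closure. It is implemented with reflected
  ghost nodes, equivalent on smooth fields to one-sided second-order
  boundary stencils of a differentiation matrix.
- The degenerate term uses the identity `∇·(n∇n) = ½∇²(n²)`, inheriting the
  Laplacian's closure. Under trapezoid quadrature weights (half-weight at
  boundary nodes) the semi-discrete diffusion operators telescope exactly,
  so the conservation law above holds to machine precision in the discrete
  functional (measured drift ~1e-15 over t = 50); with uniform weights it
  would only hold to O(dx²).
- Forward Euler in time. The step is `safety · h²/(2 · ndim · D_max)` with
  `safety = 0.2`, where `D_max` is the largest effective diffusivity
  (1 for nutrient, `D_mi` for dead cells, `D_n·max(n)` for the degenerate
  term), additionally capped at `0.1 / J` with `J` a crude bound on the
  fastest reaction rate. The step is held fixed during a run for
  reproducibility and recomputed only when `max(n)` has grown by more than
  10% (the degenerate diffusivity scales with density).
- Negativity: values in `(−1e−12, 0)` are rounding artifacts and are
  clamped to zero each step; anything below `−1e−12` (or any NaN/Inf)
  aborts the run naming the field and node — a genuine undershoot means the
  step size was too large and must not be silently repaired.
- Default resolution `dx = dy = 0.5`; halving `dx` changes the measured
  no-death expansion speed by ~0.8%. The shape-translation diagnostics use
  `dx = 0.25`, where front-marker interpolation error is a few per mille.

## Diagnostics

- **Front position**: outermost crossing of `n = 0.05`, linearly
  interpolated in the bracketing cell. The threshold is a convention; the
  acceptance suite verifies that speed orderings are unchanged for
  thresholds 0.02 and 0.1.
- **Expansion speed**: least-squares slope of the front trace over the
  final 50% of the run, discarding the inoculum transient.
  `relative_variation` compares the fitted slopes of the two window halves
  relative to the full-window slope. A raw spread of finite-difference
  speeds was rejected for this purpose: the interpolated front marker
  wobbles by ~±0.04 (sub-cell phase) as the sharp front crosses grid cells,
  which at `dx = 0.5` masquerades as ~10% apparent speed variation on a
  perfectly steady front; half-window slopes average that noise out and
  respond to genuine acceleration.
- **Profile classification**: *pulse* when the core density `n(0)` is below
  half the peak (proliferating rim around a necrotic interior), otherwise
  *wavefront*; *extinct* for an identically zero profile. FWHM by
  interpolated half-maximum crossings (pulses only).
- **Petal amplitude**: the front contour `x_f(y)` is reduced to the
  amplitude of its `cos(qy)` component by trapezoid quadrature, which is
  spectrally accurate over whole periods; admissible wavenumbers are
  `q = 2πk/Ly` (integer periods, zero normal derivative at the walls).

## Experiments and problem sizes

1D runs start from the Gaussian inoculum `n = exp(−x²)`, `g ≡ 1`, no dead
cells, on the half-line with a symmetry plane at `x = 0`. 2D stability runs
take the 1D solution at a late base time, corrugate every field by
`(1 + δ cos(qy))` with `δ = 0.1`, `q = 6π/50 ≈ 0.3770`, and track the petal
amplitude.

Two geometry scales ship with the registry. The `full` scale uses the
full-size domains (`x ∈ (0, 150)`, `y ∈ (−50, 50)`, base time 300, horizon
100; `x ∈ (0, 700)` for the linear-diffusion control). The default `scaled`
geometry keeps every qualitative outcome while running the full suite in
about two minutes: 1D domain `x ∈ (0, 100)` to `t = 150`; 2D domain
`x ∈ (0, 110)`, `y ∈ (−25, 25)` (three perturbation periods) to `t = 60`
from a base state at `t = 150`. Domain lengths were chosen from the
measured speeds so that fronts stay clear of the outer wall: the no-death
front (speed ≈ 0.35) ends near `x ≈ 75`; the linear-diffusion control
(speed ≈ 1.36 ≈ 2√D_n) needs `x ∈ (0, 320)` with a base domain of 340. The
dominant-RCD regime approaches its travelling wave slowly, so its 2D base
state uses `t = 250`, by which the residual speed drift is below 2%. The
shape-translation check compares snapshots 5 time units apart: the front
superposes to ~1% of peak, while the colony interior far behind the front
still relaxes slowly, so widely separated snapshots would conflate that
relaxation with translation failure.

## What the experiments do and do not show

The scenarios are self-contained numerical experiments, not fits to data:
initial conditions are analytic, there is no noise, and the pipeline is
fully deterministic. Qualitative conclusions (speed orderings, composition
patterns, stability orderings) are robust across the two geometry scales
and to the front-marker threshold; absolute speeds and petal amplitudes
depend on the parameter choices and comparison times and carry no
experimental units. Real colonies add ECM mechanics, heterogeneous agar,
and stochastic inoculation, none of which are modelled.

## Known limitations

- Explicit Euler stepping only: the diffusive step bound makes very fine
  grids expensive (`dt ∝ dx²`); no implicit or adaptive-order integrators.
- The perturbation analysis is numerical; no travelling-wave or linear
  eigenvalue analysis is provided (the coupled system is eight-dimensional
  in the travelling frame, and such analysis is out of scope).
- Petal amplitudes are measured for the seeded mode `q` only; harmonics
  generated nonlinearly at late times are not tracked, so amplitude values
  are meaningful while the perturbation remains moderate.
- The front marker fails (by design) once a front reaches the outer wall;
  domain sizes in the registry are chosen to avoid this within their
  horizons.
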