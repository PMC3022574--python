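# Methods

## Model

The package describes a treadmilling actin array in one spatial dimension,
x ∈ [0, L_sys], x = 0 at the leading edge, in steady state.  The network is a
concentration field, not a collection of explicit filaments.  Its
assumptions: nucleation happens only at x = 0 at a constant rate N₀;
filaments are straight in projection and transported rearward rigidly at the
network growth speed V (incompressible network, no differential retrograde
flow, no adhesion mechanics); plus-end capping is an irreversible Poisson
process; subunit aging is a linear four-state system (ATP → ADP, then
competitive ADF/cofilin binding/unbinding vs. effectively irreversible
tropomyosin binding); depolymerization happens only at free (debranched)
minus ends and, in confined mode, instantaneously in the convergence zone at
x = L_sys; monomers return to the edge by Fickian diffusion.  Severing,
annealing, formin nucleation, uncapping, and cooperative binding are outside
the model.

A filament is parametrized by its uncapped age t_uc and capped age τ_c.
Because every plus end starts at the edge and minus-end recession depends
only on total age t, the minus end of any filament of age t sits at
x_m(t) = V t − δ_p S(t), where S is the cumulative minus-end loss.  The
package exploits this only for verification (an exact closed form for F and
M); the production pipeline follows the group-integral formulation: the
contribution of the group with capped age τ_c to F(x) is
N₀ exp(−r_cap · t_uc_min(θ, τ_c)) with θ = x − V τ_c, where t_uc_min inverts
the tabulated length law L(t_uc, τ_c).

### Dwell-time identification

State probabilities are evaluated at the filament age t rather than the
subunit dwell time.  The minus-end subunit is the oldest subunit in its
filament, so for minus-end chemistry the two coincide up to the capping
delay; the error this induces in J_d is bounded by the conservation checks
below.  The same identification maps regulator-bound F-actin profiles as
F(x)·p_ac(x/V) and F(x)·p_tm(x/V), and the minus-end rate entering
J_d(x) = M(x) r−(x/V).

## Numerics

* Kinetics: the four-state linear system is solved by eigendecomposition of
  the 4×4 generator (exact at every grid time); an RK fallback guards
  near-defective rate coincidences.  S(t) is a trapezoidal cumulative sum on
  the dt grid.
* Group integrals: trapezoidal in τ_c on a grid with spacing dtau_c, with an
  exact partial cell appended at the Heaviside cut τ_c = x/V (the cut-value
  of the integrand comes from the age map, which gives the minimal surviving
  age at each x in closed form).  The inversion t_uc_min is a linear
  interpolation of the strictly monotone tabulated length row; monotonicity
  requires r+ > s_ac·k⁻, which the solver enforces by bracketing c(0) away
  from the slow-growth regime.
* Deposited fields (M, length histograms, the ensemble oracle): each
  filament cohort's minus end or length is accumulated through a
  piecewise-linear mass CDF interpolated at bin edges rather than raw
  histogram binning.  Minus-end positions collapse onto a nearly
  one-dimensional comb (x_m depends almost only on age), which raw binning
  aliases at the several-percent level; CDF deposition removes the aliasing
  while keeping the binning construction.
* Uncapped-time truncation: the population is truncated at
  t_uc_max = 10/r_cap (survival e⁻¹⁰ ≈ 5·10⁻⁵).  The group integral for F
  closes the t_uc tail analytically, so F is effectively untruncated;
  deposited statistics carry the truncation, which is matched in the
  semi-analytical oracle when comparing.
* Capped-time horizon: adaptive — the earlier of complete depolymerization
  of the oldest cohort (S(t_uc_max + τ) = r+ t_uc_max) and transport across
  the box.  A diagnostic flags any residual truncated group density.
* Diffusion: double cumulative trapezoid of J_d; the gradient constant from
  the rear boundary condition, the offset from the total-actin closure, in
  that order.  In unconfined mode the closure averages c + F over the full
  enlarged box (the box is grown until rear F < 10⁻³ µM, so the result is
  insensitive to the box at the sub-percent level; growth jumps to ~1.05×
  the estimated compact support of F, never less than 1.5× the current box).
* Fixed point: damped substitution c0 ← c0 + damping·(c0_out − c0_in)
  (damping 0.5) inside a sign bracket; proposals leaving the bracket fall
  back to bisection.  The map is monotone decreasing in c(0), so the
  bracket is safe.  Stop at |c0_out − c0_in| < 0.05 µM, cap at 200
  iterations, error with the residual trace on failure.

### Default discretization and problem sizes

dx = 0.02 µm and dt = 0.01 s for confined solves (501 spatial nodes,
~4500 capping-time groups); scans and unconfined solves use dx = 0.1 µm and
dtau_c = 10·dt, the package's coarser sweep setting.  Halving the baseline
resolution moves c(0) by well under 1%.  The diffusion scan covers
D ∈ {1, 2, 3, 5, 7, 10} µm²/s; the lamellum-size bisection runs on log₁₀ D
over [0.3, 2] µm²/s.  These sizes solve the baseline in seconds and the full
acceptance sweep in about half a minute.

## Parameters

All defaults live in `ModelParameters` (units documented per field): on/off
rates of the plus end (12 µM⁻¹s⁻¹, 1.4 s⁻¹), ADP minus-end off-rate
0.3 s⁻¹ with 30-fold cofilin enhancement, capping 1 s⁻¹, cofilin binding
0.5 s⁻¹ / unbinding 0.2 s⁻¹, tropomyosin binding 0.2 s⁻¹, hydrolysis
0.3 s⁻¹, debranching 0.5 s⁻¹, D = 5 µm²/s, total actin 350 µM, plus-end
density 440 µM, membrane resistance 100 pN/µm, sheet height 0.17 µm,
projected increment δ_p = 2.2 nm, system length 10 µm.  η = 602.2 µM⁻¹µm⁻³
is a fixed unit conversion and cannot be overridden.  k_BT defaults to
4.1 pN·nm (≈298 K); no temperature is part of the parameter set, so this is
a package choice, exposed as a field.

Two conventions for capping-rate variation: the default holds the
nucleation rate N₀ fixed (plus-end density B_eff = N₀/r_cap and load per
filament then vary with r_cap — this is what the capping scans probe); a
`fixed_B` mode holds the plus-end density instead.  At the baseline capping
rate the two coincide.

ATP-bound subunits at the minus end are assigned the ADP off-rate: no
separate literature value exists, and minus ends are almost surely ADP by
debranching time (hydrolysis and debranching rates are comparable).

## Verification strategy

Three independent routes check the pipeline:

1. Constant minus-end rate: with r− ≡ r all pieces are elementary.  F is in
   closed form; mean length and length histograms reduce to elementary
   per-group expressions integrated by fine quadrature.  The oracle accepts
   the pipeline's truncation horizon so the comparison isolates
   discretization error; agreement at baseline resolution is ~0.4% across
   F, L_mean and histograms (the tolerance asserted is 5%).
2. Ensemble brute force: a deterministic midpoint quadrature over the
   (t_uc, τ_c) population on independent grids, depositing spans and minus
   ends.  Deterministic by design — no Monte Carlo noise in acceptance
   checks.  Agreement: F within 2%, M and J_d within 5%, tightening
   monotonically under refinement.
3. Age-map closed form: F = B exp(−(r_cap/r+) S(a(x))) and
   M = r_cap F/(r+ − r−(a(x))) with a(x) the inverse of x_m(t).  Exact for
   the full aging kinetics; used as a test oracle only.

Conservation diagnostics on the converged baseline: state probabilities sum
to 1 (10⁻⁶); mean(c + F) equals the total actin A to 0.1% (exact by
construction up to quadrature); global flux balance V F(0) = ∫J_d + V F(L)
to 5% (measured ~0.7%); the pointwise zero-total-flux identity
D c′(x) = V F(x) within the mass-balance budget (measured ~1%).

## Measured-feature conventions

* Network length L_net: first x where F drops below 5 µM, linearly
  interpolated; +∞ when the confined network fills the box.
* "Maximum" rear filament length: the visible support of the rear length
  histogram — the length where P(L) falls below 1% of its modal value.  A
  literal maximum is set by the truncation horizon (the tail is
  exponential), so a density-based support is the meaningful observable.
* Depolymerization-peak uniqueness: wiggles below 0.5% of the peak value are
  ignored (residual quadrature ripple).
* Power-law exponents: unweighted least squares on log–log values over
  converged scan cells only; fits with fewer than four points are refused.

## What passing tests do and do not show

There is no synthetic-data generator and no external data: the model is
self-contained, and the "study conditions" are the parameter defaults above.
Passing tests show that the implemented equations reproduce the model's
internal balances, its semi-analytical limits, and the published magnitudes
and scalings at those parameter values.  They do not validate the biological
assumptions (rigid transport, instantaneous convergence-zone
depolymerization, no severing), and rear filament lengths are known to be
shorter than electron-microscopy values for real lamella, a recognized
limitation of the severing-free model.

## Known limitations

The unconfined closure averages total actin over the enlarged box; the
alternative (renormalizing to the physical cell volume) is not modeled.  The
transport-age identification makes J_d slightly inconsistent with −V F′ near
the edge (bounded by the mass-balance budget).  Confined solves with very
small growth rates (r+ approaching the cofilin-enhanced minus-end rate) are
rejected as infeasible rather than solved, since filament length then stops
being monotone in uncapped time.
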