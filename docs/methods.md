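# Methods

## The lattice model of cooperative decoration

An actin filament is treated as a one-dimensional lattice whose sites are
regulatory units: one Tn-Tpm ligand occupies seven contiguous actin monomers
(site length 0.0385 µm, the canonical thin-filament half-pitch). Binding
follows

- association: an empty site binds free ligand with probability
  `k1·[L]·dt` per iteration, independent of its neighbors (association is
  taken to be diffusion/activation controlled);
- dissociation: a bound ligand with `n ∈ {0, 1, 2}` bound nearest neighbors
  unbinds with probability `k_minus1·σ^(−n)·dt`. The cooperativity parameter
  σ > 1 therefore acts only on the dissociation rate, producing
  nucleation/elongation behavior: isolated ligands are short-lived, ligands
  inside runs are stabilized by a factor σ per contact. Lattice ends
  contribute no neighbor; there is no periodic boundary.

The scheme satisfies detailed balance with respect to the nearest-neighbor
lattice-gas stationary law `π(config) ∝ z^bound · σ^pairs` with
`z = k1[L]/k_minus1`, which the tests verify by exact enumeration on 3-site
lattices (total-variation distance < 0.02).

**Update scheme.** Synchronous-sweep fixed-timestep kinetic Monte Carlo: all
events in one iteration are decided from the pre-step state. This matches an
"iteration" picture of the dynamics and is accurate when per-event
probabilities are small; configurations are rejected outright when any
probability reaches 1, and defaults keep binding probabilities ≤ 0.1
(the defaults put the isolated-ligand unbinding probability at 0.25 per
step, a deliberate trade-off that reaches steady state within ~100
iterations).

**Finite ligand pool.** The ensemble's `M` sites represent a site
concentration, so one molecule ↔ `site_conc/M` nM. Binding decrements an
integer free-molecule counter (excess binding candidates are rejected
uniformly at random), so ligand count is conserved exactly at every step — an
invariant asserted in the tests.

**Stoichiometric mode.** Thin filaments are reconstituted at constant 1:1:7
Tn:Tpm:actin stoichiometry, so the site concentration co-varies with the
ligand total across the 12.5–750 nM titration. `total_site_conc=None`
(default) reproduces this: at each titration point the lattice represents a
site concentration equal to that point's ligand total, and the free pool
starts at exactly one molecule per site. A fixed site concentration and a
fixed-free (grand-canonical) mode are also available; the latter is used for
analytic cross-checks and for decorating synthetic filaments at a prescribed
free concentration.

**Steady state.** A point is converged when the mean of θ over the last 20
iterations changes by less than 10⁻³ relative to the preceding window.  At
the calibrated defaults every titration point converges in 40–100 iterations;
non-convergence within `max_iterations` is flagged on the result, not raised.
Steady-state values (θ, free ligand, neighbor tallies) are means over the
final window; the per-point SD is taken across per-lattice bound fractions or
across replicate sweeps.

## Calibration

Absolute rates are not identifiable from an equilibrium isotherm, only the
ratio `k1/k_minus1` and σ. Calibration therefore proceeds exactly as a
practitioner would:

1. For each σ on a coarse grid (1, 1.5, 2, 3, 5, 10), bisect `log(k1/k_minus1)`
   until the Hill fit of the simulated isotherm matches the experimental
   saturation dissociation constant (~0.5 µM) to 5 %. Each objective
   evaluation averages the isotherm over 3 replicate sweeps under fixed seeds,
   making the bisection deterministic.
2. Keep the σ whose fitted Hill coefficient is nearest the experimental
   value (1.2). On the default grid this selects σ ≈ 1.5–2 (fitted n_H 1.14
   and 1.25 bracket the target); the packaged defaults are σ = 2.0 and
   k1/k_minus1 ≈ 1.1×10⁻³ nM⁻¹ with k_minus1·dt = 0.25.

The fitted Hill coefficient increases monotonically with σ (measured: 1.0 at
σ=1, ~1.25 at σ=2, ~2.1 at σ=10, ~4.3 at σ=30), so the grid selection is
well-behaved.

## Neighbor-class abundances

At each steady-state titration point every bound ligand is classified by its
number of bound nearest neighbors: isolated (n=0), one-side (n=1), two-side
(n=2); a site at a lattice end can have at most one neighbor. Per-point class
fractions always sum to 1. The integrated composition is the area under each
class's abundance curve across the titration (trapezoid on the log₁₀
free-concentration axis, the scale on which such curves are plotted),
normalized so the three areas sum to 100 %. Counts instead of fractions, and
a linear concentration axis, are available as options.

A structural observation, computed by the package itself: a mildly
cooperative isotherm (n_H ≈ 1.2) and near-complete clustering of bound
ligands are mutually exclusive on this titration. Under the stoichiometric
design, free ligand depletion caps coverage near `1 − K_d/750 nM` even for a
step-like isotherm, so at the σ consistent with n_H ≈ 1.2 the conditional
neighbor occupancy stays in the 0.3–0.7 range and the integrated composition
is ≈ 48/40/13 % (isolated/one-side/two-side). A two-side share above 90 %
would require mean runs of > 40 sites at near-full coverage, which both the
coverage cap and the n_H constraint rule out (driving σ up pushes the fitted
n_H past 4 before the composition gets there). Additionally, with lattice
ends counted as contributing no neighbor, two ligands per fully covered
40-site lattice are one-side by construction, placing a ≈ 5 % floor on the
one-side class whenever the two-side class dominates.

## Mean-field oracle

The deterministic companion integrates

    dθ/dt = k1·[L]_t·(1 − θ) − k_minus1·σ^(−⟨n⟩_t)·θ

with fixed-step RK4 at the simulation time step, `[L]_t` from mass
conservation, and ⟨n⟩ = 2p from the quasi-chemical pair closure
`σ = p(1 − 2θ + θp) / (θ(1−p)²)` (the infinite-lattice equilibrium pair
probability at the current coverage; p = θ at σ = 1). At σ = 1 the equation
reduces to Langmuir kinetics and matches the closed-form relaxation to 10⁻⁶;
the stochastic ensemble mean tracks it within Monte Carlo error. The
equilibrium fixed point of the rate balance is exposed separately
(`equilibrium_theta`) and agrees with the long-time ODE limit.

## Synthetic micrographs

The generator emulates surface-deposited, well-separated thin filaments
imaged by wide-field epifluorescence:

- **Geometry** — filament lengths are left-truncated exponential (default
  mean 40 sites = 1.54 µm, matching the simulated lattices; the truncated law
  is `min + Exp(mean − min)`, so the sample mean equals the nominal mean).
  Curves are persistent random walks with bounded per-step turning,
  rejected if self-crossing or leaving the field.
- **Decoration** — either the lattice simulator's steady state at a fixed
  free concentration, or `hill_direct`: overall coverage set by the Hill law
  and occupied sites laid down as alternating geometric runs and gaps. The
  mean run length `κ/(1 − coverage)` (κ = 8 sites ≈ 0.3 µm) grows with
  coverage, emulating nucleation clusters that coalesce toward full
  decoration; geometric memorylessness makes a Bernoulli(coverage) initial
  state exactly stationary, so the marginal site occupancy equals the target
  coverage.
- **Rendering** — intensity is deposited along the curve at 0.3 px spacing
  (actin everywhere, Tn/Tpm over occupied sites only), blurred with an
  isotropic Gaussian PSF (σ = 0.106 µm ≈ 250 nm FWHM) at 15 px/µm, then
  background, Poisson shot noise and Gaussian read noise are applied.
  Rendering is linear in the channel gains and bit-reproducible from the
  scene seed.

Not emulated: photobleaching, filament bundling/aggregation, chromatic
misregistration beyond sub-pixel scale, depth structure (2-D only), or
camera-specific noise (a Poisson + Gaussian model stands in). Passing
recovery tests therefore demonstrate correctness of the analysis chain under
idealized optics, not robustness to every real-microscope artifact.

## Image analysis

- **Binarization** — channels are segmented from the Sobel gradient
  magnitude. For a diffraction-blurred ridge the gradient peaks flank the
  ridge and, along the filament axis, peak at intensity steps — near the true
  boundaries of decorated runs — so filling between edges localizes region
  ends well. The default threshold is `median + 8·MAD` of the gradient
  magnitude: scale-invariant and robust to arbitrarily sparse foreground
  (a fixed quantile of the gradient distribution sits inside the noise floor
  when filaments occupy a few percent of the field; quantile and Otsu modes
  remain available). Edge masks are closed (disk radius 1), hole-filled and
  cleared of objects under 12 px.
- **Colocalization** — decorated regions are the pixelwise AND of the Tn and
  Tpm masks after a 1 px dilation of each (absorbing sub-pixel chromatic
  misregistration; 0 px gives a strict intersection).
- **Skeletons** — the actin mask's topological skeleton is split at branch
  pixels (more than two 8-neighbors); remaining components are ordered simple
  paths; cycles and paths under 10 px are dropped. Path length uses √2
  weighting for diagonal steps plus one pixel, so an n-pixel straight trace
  has length n.
- **Statistics** — θ is the pooled ratio (sum over filaments before
  dividing); per-filament ratios are retained for replicate-level tests.
  Zero-lag cross-correlation is the Pearson coefficient of two profiles
  sampled at the skeleton coordinates; zero-variance profiles are excluded
  from image means with a logged count rather than assigned a value.
  End-to-end, measured θ tracks ground-truth coverage within ±0.05 at
  coverages 0.1–0.9 under default noise.
- **Length fits** — filament and decorated-run length samples are fitted by
  the truncation-aware exponential MLE `mean = mean(x − truncation)`
  (SE `mean/√n`), which removes the `+truncation` bias of the naive mean
  under a minimum-length filter.

## Hill fitting

The default model is `θ = A·[L]^n_H/(K_d^n_H + [L]^n_H)`, so K_d carries
concentration units; a `literal` variant with an un-exponentiated K_d in the
denominator is available behind a flag for comparability with legacy fits,
and both are covered by tests. Saturation isotherms fix the plateau A = 1;
correlation isotherms fit A freely, since correlations saturate below 1 in
noisy data. Weights are 1/sd² when per-point SDs are available. K_d is
initialized at the concentration nearest half-max with n_H = 1, plus four
jittered restarts; asymptotic standard errors come from the curvature at the
optimum scaled by residual variance. Fewer than 4 points or a flat response
raises a fit error rather than returning meaningless parameters.

Free-ligand accounting offers both conventions — θ-corrected
(`free = total − θ·site_conc`, clamped at 0 with a warning) and
free ≈ total — because published workflows differ; the θ-corrected form is
the default throughout.

## Validation problem sizes

The test suite and the results script run at the study scale where it is
cheap (100 lattices × mean 40 sites, 7-point titrations, 5 replicate sweeps)
and at reduced image sizes where rendering dominates: recovery experiments
use 5 images of 384×384 px with 25 filaments per titration point, and 20
replicate titrations for the end-to-end parameter-recovery check (median
K_d error ≈ 15 %, median n_H error ≈ 0.12 at that size). Group comparisons
use pooled-variance two-tailed t-tests at α = 0.05 (Welch available).

## Known limitations

- The synchronous update is approximate near per-event probabilities of
  order 1; calibration absorbs the resulting small bias in the effective
  K_d but σ retains a scheme-dependent meaning.
- Only the rate ratio is calibrated; absolute time (and hence the meaning of
  one iteration in seconds) is arbitrary.
- The mean-field ⟨n⟩ closure assumes quasi-equilibrium pair statistics on an
  infinite lattice; it is exact at σ = 1 and increasingly approximate for
  strong cooperativity or far from steady state.
- Skeleton-based θ slightly biases decorated-run ends by the PSF width in
  each direction; the Sobel edge convention cancels most, and the residual
  is within the ±0.05 recovery envelope at default settings.
- Crossing filaments are split at branch points and fragments below the
  minimum length are discarded, under-sampling very short or dense filament
  populations.
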