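# thinfil

Quantitative analysis of troponin–tropomyosin (Tn-Tpm) decoration of actin
filaments, for researchers studying cooperative assembly of the cardiac thin
filament by multichannel fluorescence microscopy.

Cardiac muscle regulation depends on Tn-Tpm regulatory units — one troponin
complex plus one tropomyosin dimer spanning seven actin monomers — binding
head-to-tail along F-actin. In triple-labeled preparations (Tpm, Tn, and
F-actin each carrying a distinct fluorophore), decorated and undecorated
filament regions can be distinguished directly, turning micrographs into
binding curves. This package provides the complete desk workflow:

- **`thinfil.synth`** — synthetic three-channel micrographs with known ground
  truth: filaments with single-exponential length statistics, cooperatively
  clustered decoration, ~250 nm Gaussian PSF at 15 px/µm, shot and read noise.
- **`thinfil.imaging`** — Sobel-based segmentation, skeletonization into
  ordered single-pixel traces, decorated-region identification by Tn ∧ Tpm
  colocalization, and the two per-image statistics: the saturation

  θ = Σᵢ‖x⁽ⁱ⁾_Tn-Tpm‖ / Σᵢ‖x⁽ⁱ⁾_actin‖

  (pooled decorated-to-total skeleton pixel ratio) and the zero-lag
  normalized cross-correlation of decoration and actin intensity profiles
  sampled along the skeleton, plus exponential length-distribution fits.
- **`thinfil.isotherm`** — binding isotherms and weighted nonlinear
  least-squares fits of the Hill equation

  θ([L]) = [L]^n_H / (K_d^n_H + [L]^n_H),

  yielding the apparent dissociation constant K_d and Hill coefficient n_H
  with asymptotic standard errors; two-tailed t-tests between conditions.
- **`thinfil.latticesim`** — kinetic Monte Carlo simulation of ligand binding
  to one-dimensional lattices. Each site binds free ligand with rate
  k₁[L] and unbinds with rate k₋₁σ^(−n), where n ∈ {0, 1, 2} counts bound
  nearest neighbors and σ > 1 produces nucleation/elongation cooperativity.
  Includes exact ligand-count conservation, neighbor-class analytics, a
  deterministic mean-field oracle, and iterative calibration of k₁/k₋₁ (and σ
  on a coarse grid) against an experimental K_d.
- **`thinfil.cli`** — `thinfil simulate|render|analyze|fit|report`
  orchestration with manifests for bit-reproducible runs.

## Worked example

```python
import numpy as np
from thinfil import latticesim as ls, synth, imaging
from thinfil.isotherm import fit_hill

# simulate the titration at the calibrated defaults and fit the Hill equation
iso, results = ls.simulate_isotherm(ls.SimConfig(seed=1))
fit = fit_hill(iso, fix_scale=1.0)
print(f"Kd = {fit.kd/1e3:.2f} +/- {fit.kd_se/1e3:.2f} uM, "
      f"n_H = {fit.n_h:.2f} +/- {fit.n_h_se:.2f}")

# render one synthetic field and measure it
spec = synth.SceneSpec(n_filaments=25, seed=0, hill_params=(500.0, 1.3, 500.0))
img, truth = synth.make_scene(spec, synth.RenderConfig(seed=1))
table, summary = imaging.analyze_image(img)
true_cov = sum(g.occupancy.sum() for g in truth) / sum(g.n_sites for g in truth)
print(f"scene: true coverage {true_cov:.3f}, measured theta {summary['theta']:.3f}")
```

prints

```
Kd = 0.51 +/- 0.03 uM, n_H = 1.17 +/- 0.04
scene: true coverage 0.482, measured theta 0.491
```

The first two lines are the simulated steady-state binding isotherm of 100
lattices (exponentially distributed site counts, mean 40) titrated from 12.5
to 750 nM total ligand at constant 1:1:7 Tn:Tpm:actin stoichiometry: the
fitted K_d is the free-ligand concentration at half saturation and n_H > 1
reflects nearest-neighbor cooperativity. The last line shows that the image
pipeline recovers ground-truth coverage from a rendered noisy scene to within
about one percentage point.

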