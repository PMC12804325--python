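# a0sim — measurement errors and minimum ablative margins, in silico

Thermal ablation of liver tumors is judged successful when the
post-ablation imaging shows a sufficient **minimum ablative margin**
(MAM): the smallest 3D distance between the tumor boundary and the
ablation-zone boundary, measured by co-registering pre- and
post-ablation scans and segmenting both structures. Clinical practice
commonly requires an observed MAM of 5 mm ("A0 ablation", by analogy
with R0 resection). But the observed margin is a *measurement*:
registration error, contouring error and slice thickness distort it,
while tissue shrinkage and microscopic satellite lesions make the true
microscopic tumor differ from the imaged one. How large an observed
margin is actually needed before the *true* margin is positive with
high confidence — and is the 5-mm rule ever reliable?

`a0sim` answers this with a Monte Carlo simulation on synthetic 3D
voxel phantoms. For each simulated case it builds a tumor sphere
(diameter ~ U(10, 30) mm) and a concentric ablation zone (target margin
~ U(−5, 10) mm), applies biological effects to the true tumor and
technical errors to the imaged masks, and measures both the true and
the observed MAM with an exact spacing-aware surface distance. Pooling
10,000 such cases per parameter configuration, it fits a logistic model

&nbsp;&nbsp;&nbsp;&nbsp;logit P(MAM_true > 0 | MAM_observed = x) = β₀ + β₁ x

and reports the **A0 threshold** x_A0 = (logit 0.99 − β₀)/β₁, the
observed margin at which true complete coverage is 99% probable, plus
the empirical reliability of the 5-mm rule,
P(MAM_true > 0 | MAM_observed ≥ 5).

The error models (defaults in parentheses): registration shift
magnitude ~ N(0, ε_reg) mm along a random axis (1 mm); independent
global boundary offsets for each segmentation mask (nominal 1 mm);
nearest-neighbour cranio-caudal resampling to the slice thickness
(1 mm); radial tumor shrinkage fraction ~ N(φ, 0.05) clamped at 0
(φ = 0); one tangent satellite lesion of radius ~ U(0.5, 2.5) mm with
presence probability p (0). See `docs/methods.md` for the model
details and the calibrated realization of the under-specified noise
terms.

## Worked example

```python
from a0sim import A0Model, SimulationParams

# ablation-confirmation software with a 3 mm segmentation error,
# everything else at the 1 mm baseline
params = SimulationParams(segmentation_sd_mm=3.0, seed=11)
res = A0Model.from_params(params, n_sims=2000).fit()
print(res.summary())
```

prints

```
A0 threshold estimation (logistic coverage model)
==========================================================
records used:            2000
records excluded:        0
target probability:      99.00%
beta0 (intercept):        0.3283  (se 0.0809)
beta1 (per mm):           0.8046  (se 0.0374)
A0 threshold x_A0:       5.3 mm
P(covered | obs >= 5mm): 0.9981
5-mm rule reliable:      no
```

Read: with a 3 mm contouring error the fitted sigmoid crosses 99%
coverage probability at an observed margin of ≈5.3 mm, so demanding
5 mm on the screen is *not* quite enough to guarantee (at 99%) that the
microscopic tumor was fully destroyed; among simulated cases that did
show ≥5 mm, 99.8% were truly covered. At the 1 mm baseline the same
computation gives x_A0 ≈ 3.5 ± 0.2 mm and the 5-mm rule holds.

The same machinery runs one-factor sweeps and 2D grids:

```python
from a0sim import SimulationParams, run_sweep, run_grid, plot_coverage_curves

base = SimulationParams(seed=11)
sweep = run_sweep(base, "registration", [1, 3, 5], n_sims=2000)
print([round(r.x_a0_mm, 1) for r in sweep])   # [3.9, 4.1, 6.3]
plot_coverage_curves(sweep, "curves.png")

matrix, _ = run_grid(base, seg_values=[1, 2, 3], reg_values=[1, 2, 3],
                     n_sims=2000)   # A0 per (seg, reg) cell
```

or from the shell:

```bash
a0sim single --n 2000 --seed 7 --out results/baseline
a0sim sweep --vary segmentation --values 1,3,5 --n 2000 --seed 7 --out results/seg
a0sim grid --seg 1:3 --reg 1:3 --n 2000 --out results/grid
a0sim report --in results/seg --out figures/
a0sim mam --tumor tumor.nii.gz --ablation ablation.nii.gz
```

`a0sim report` regenerates the sweep sigmoids, the A0 contour over
segmentation × registration error and the 5-mm verdict purely from the
stored CSV/JSON results.

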