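# fdglong

Longitudinal FDG-PET quantification and statistics on synthetic phantom
cohorts: partial-volume-corrected SUVR imaging, region-level
mixed-effects modelling of an ApoE ε4 carrier-by-time interaction,
voxelwise paired-t cluster inference with permutation-based
family-wise error control, and conversion/survival analysis.

## The problem

In longitudinal PET studies of mild cognitive impairment, the question
is whether ApoE ε4 carriers lose glucose uptake faster than
non-carriers, and *where*. Two methodological obstacles dominate:

1. **Partial volume effects.** Scanner resolution (~8 mm FWHM) is
   coarse relative to structures like the amygdala or caudate, so
   signal spills between regions; with atrophy, this biases
   longitudinal change estimates. The package implements the
   iterative reblurred Van Cittert deconvolution

       f₀ = g,   f_{k+1} = f_k + α · h ⊗ (g − h ⊗ f_k)

   with α = 1.5, an 8 mm Gaussian PSF h, stopped when the relative
   percent change of the corrected image falls below 1 %.

2. **Inference over time and space.** Regional SUVR trajectories
   (SUVR = uptake relative to cerebellum) are modelled per region as

       suvr ~ sex + education + baseline_age + month + carrier + carrier:month
              + (1 | subject)

   by REML, testing the carrier:month interaction (Wald z). Voxelwise,
   follow-up is compared to baseline with a paired t-test; clusters
   formed at one-tailed p < .001 are tested at cluster-level
   FWER < .05 using the exact sign-flip permutation null of the
   maximum cluster extent, with peak effect sizes reported as
   Z = Φ⁻¹(F_t(t)) and Cohen's d = Z/√n.

Because the original image data live in a restricted repository, the
package ships a fully synthetic phantom cohort generator (atlas,
subject covariates, ground-truth trajectories, blurred noisy visit
images) with the same statistical structure, so every stage is
testable and every number below is recomputed from scratch.

## Worked example

```python
import fdglong as fl

# a 48-subject phantom cohort with study-scale regional decline
subjects, truth = fl.simulate_cohort(n_per_group=24, seed=17)
table = fl.suvr_table_from_truth(truth, subjects, noise_sd=0.005, seed=18)

print(fl.mean_percent_change(table, "parietal", "carrier"))
print(fl.mean_percent_change(table, "parietal", "non-carrier"))
res = fl.fit_roi_lmm(table, "parietal", subjects)
print(res.interaction_estimate, res.interaction_p)
```

prints

```
-1.5215776611961294   # carrier parietal decline, % per follow-up interval
-0.34036880277723874  # non-carrier decline
-0.0012325554926368358 0.0   # carrier:month interaction (SUVR/month) and its p
```

i.e. carriers lose about 1.5 % parietal SUVR per follow-up interval
versus 0.3 % in non-carriers, and the mixed model attributes the
difference to a highly significant negative carrier-by-time slope.

The image pipeline end to end (render → PVC → SUVR → models →
clusters → survival):

```python
cfg = fl.PipelineConfig(grid_shape=(28, 32, 28), n_regions=10,
                        n_per_group=12, scan_months=(0, 12, 24, 36, 48, 60, 72),
                        followup_month=72, n_permutations=200,
                        seed=0, out_dir="scratch/pipeline")
run_dir = fl.run_pipeline(cfg)   # CSV tables + manifest, byte-reproducible per seed
```

The numbered scripts under `analysis/` run the same steps as a
narrative — `01_simulate_cohort.py` through `06_conversion_survival.py`
— writing their tables to `results/`.

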