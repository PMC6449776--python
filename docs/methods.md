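# Methods

`fdglong` re-creates, end to end on synthetic data, the quantitative
pipeline of a longitudinal FDG-PET study of ApoE ε4 carriers with mild
cognitive impairment: partial-volume-corrected SUVR imaging, per-region
mixed-effects modelling of the carrier-by-time interaction, voxelwise
paired-t cluster inference, and conversion/survival statistics. This
note records the models, the numerical choices, and what the synthetic
phantom does and does not establish.

## Phantom cohort

The generator emulates a two-group cohort — 24 ApoE ε4 carriers and 24
non-carriers — scanned at months {0, 6, 12, 18, 24, 36, 48, 60, 72,
84}. Regional true uptake follows

    u(subject i, region r, month m) = a_r + b_ir + (s_gr + c_ir)·m

with per-region intercepts `a_r`, per-(subject, region) Gaussian random
intercepts `b_ir` (sd 0.09 SUVR, matched to baseline SEMs of ~0.02 at
n = 24), group-specific slopes `s_gr`, and optional per-subject slope
deviations `c_ir` (sd 0, i.e. off, by default; used by the sensitivity
experiment, where realistic between-subject heterogeneity is the whole
point). The cerebellum reference is pinned to exactly 1.0 at every
visit so SUVR and raw uptake coincide by construction.

Default slopes are calibrated so that the *mean consecutive-interval
percent change* — the summary the emulated study tabulates — hits the
study-scale values (e.g. parietal −1.5 %/interval in carriers vs −0.31
in non-carriers; amygdala and thalamus increase in non-carriers). A
naive `percent / mean-interval` conversion misses these targets by
~7 % because visit spacing is uneven and the denominator declines, so
the slope is obtained by root-finding on the exact summary.

The atlas is a seeded Voronoi parcellation of an ellipsoidal brain
mask, with names mirroring the 25-region inventory of the emulated
study. Geometry is irrelevant to the downstream mathematics; what
matters is that (a) a cerebellum reference exists, (b) small regions of
a few hundred voxels exist to expose partial-volume effects. The
small-capped regions (amygdala, caudate, hippocampus, putamen) are
assigned the deepest seed points: these are deep subcortical
structures, and placing them at the brain edge would make their
partial-volume behaviour reflect the brain/background boundary rather
than tissue–tissue contrast.

Images are rendered as the piecewise-constant regional truth
(optionally eroded by atrophy, see below), convolved with an isotropic
Gaussian PSF (default 8 mm FWHM, the uniform resolution of the
emulated study's inputs), plus additive Gaussian noise (default sd
0.02 SUVR, white). Real reconstructed-and-smoothed PET noise is
spatially correlated; `render_visit_image(noise_fwhm_mm=...)` can
smooth the noise field with a matched Gaussian, and the voxelwise
calibration experiment uses that option (see "Cluster inference"
below). Atrophy is modelled as linear fractional volume loss: at each
visit the deepest `1 − rate·month` fraction of the region's voxels (by
Euclidean distance transform, ties broken by voxel index) keeps its
uptake and the eroded shell is replaced by CSF-like uptake 0.3.

Conversion to dementia is exponential with hazards 0.0093/month
(carriers) and 0.0056/month (non-carriers), calibrated to the emulated
study's 13/24 vs 9/24 converters over 84 months, censored at the last
scan.

What the phantom does *not* emulate: anatomy (regions are Voronoi
cells), scanner effects beyond a stationary Gaussian PSF, registration
error, visit dropout (every subject completes the schedule), amyloid
or tau co-pathology, and non-linear trajectories. Tests passing on the
phantom therefore establish the correctness and calibration of the
*computations*, not clinical conclusions about real cohorts.

## Partial volume correction

The reblurred Van Cittert iteration

    f_0 = g,    f_{k+1} = f_k + α · h ⊗ (g − h ⊗ f_k)

with step length α = 1.5 and an 8 mm FWHM Gaussian `h`, stops when the
relative percent change between iterates drops below 1 % or after 30
iterations. Numerical choices:

* **Stopping norm.** "Relative percent change" is the global L1 ratio
  `100·Σ|f_{k+1} − f_k| / Σ|f_k|` — robust to isolated voxels and
  symmetric with the flux accounting.
* **Boundaries.** Convolution uses mirror (reflect) boundaries, which
  make the discrete blur exactly mass-conserving. Consequently the sum
  error of the iterates obeys `s_{k+1} − s_g = (1 − α)(s_k − s_g)`:
  it alternates sign and halves per step at α = 1.5, and the corrected
  image's total flux matches the observed image's. Starting from
  `f_0 = g` the sum error is identically zero; the geometric
  contraction is exercised through the warm-start argument.
* **No non-negativity clipping.** Classic Van Cittert ringing produces
  small negative excursions (mostly outside the brain); clipping would
  break the linear flux property, so negatives are counted and
  reported instead.
* **Divergence guard.** If the inter-iterate change grows above its
  initial value for three consecutive iterations the routine aborts;
  with 0 < α < 2 (enforced at configuration) this cannot trigger for a
  Gaussian kernel, so the guard is purely defensive.
* **Order of operations.** PVC is applied to uptake images *before*
  SUVR scaling; since SUVR is a global rescale and the iteration is
  linear, the order only matters once noise or masking enters.

At iteration counts reached under the 1 % rule (6–8 on phantoms) the
per-frequency response `1 − (1 − α ĥ(ω)²)^k` recovers low and mid
frequencies almost fully and high frequencies partially; ROI means of
small hot/cold regions move strictly toward truth (verified on every
≥5 %-contrast region of the standard 40×48×40 phantom).

## SUVR and regional summaries

SUVR divides every voxel by the mean uptake of the cerebellum label
(a single atlas label; no grey/white segmentation, which is out of
scope). The global-cortex composite is the voxel-count-weighted mean
over the fixed member union — identical to the ROI mean of the merged
mask. Percent change per region and group averages the consecutive-
interval relative changes over all intervals of all subjects (not the
endpoint-only change), matching the tabulation convention of the
emulated study.

## Regional mixed-effects model

Per region: `suvr ~ sex + education_years + baseline_age + month +
carrier + carrier:month` with a random intercept per subject (random
slope on month available as an option), fit by REML via statsmodels
MixedLM; the carrier:month coefficient is tested two-sided by Wald z.
Choices and caveats:

* The carrier main effect is included alongside the interaction (model
  hierarchy); time is continuous in months from baseline.
* Internally time is rescaled to years: with months, the random-slope
  variance is ~10⁴ times smaller than the intercept variance and the
  REML surface becomes ill-conditioned — optimisers reported
  convergence at spurious stationary points with standard errors off
  by two orders of magnitude against a per-subject-slope oracle. The
  fit also races several optimisers and keeps the converged result
  with the highest restricted likelihood. All reported quantities are
  rescaled back to per-month units.
* No multiple-testing correction across regions: regions are flagged
  at per-ROI p < .05 with a negative estimate, matching the reporting
  convention being reproduced. This is a known limitation, not an
  endorsement.

With zero noise the fit recovers the injected interaction exactly (to
1e-10 in practice); under the null the Wald test's type-I error sits
inside the 95 % binomial band at n = 200 replicates; on a fixed
deterministic dataset the estimate agrees with r-lme4 to 1e-12 and the
SE to ~1e-8.

## Voxelwise cluster inference

Follow-up vs baseline SUVR images are compared with a per-voxel paired
t statistic (decline = negative t; zero-variance voxels are masked
out). Suprathreshold voxels at the one-tailed cluster-forming
threshold p < .001 are grouped with 18-connectivity (the convention of
the SPM software family). Cluster-level FWER uses the null
distribution of the **maximum cluster extent** over random sign flips
of the pair differences — a substitution for Gaussian random-field
theory that is exactly valid at any sample size; corrected p-values
are `(1 + #{perm max ≥ observed}) / (1 + B)`, or exact proportions
when all 2ⁿ sign patterns are enumerated (requested permutation counts
above 2ⁿ are capped at exhaustive enumeration). Because the mechanism
differs from random-field theory, numerical cluster p-values are not
expected to match SPM's; extent thresholds are implied by the
permutation null rather than configured.

Peak reporting follows the probability-matched convention: Z =
Φ⁻¹(F_t(t; df)) evaluated through the survival function on the
positive branch for tail accuracy, and Cohen's d = Z/√n — the
convention verified against every spot-checked peak row of the
emulated study (e.g. Z 5.33 → d 1.09 at n = 24).

**Calibration and noise colour.** The FWER calibration simulates 200
signal-free cohorts (12 pairs, 16³ grid, 500 permutations each) with
PSF-smoothed noise. Under *white* noise the suprathreshold set at
p < .001 is a handful of isolated voxels, the max-extent null is
concentrated on {0, 1}, and the test becomes strictly conservative
(measured FWER ≈ 0.015) — valid but below the nominal band purely
through discreteness. With spatially correlated noise, as in real
smoothed PET, extents vary enough for the empirical FWER to sit inside
the band (≈ 0.04–0.075 across seeds). Power is checked separately: a
focal 0.06-SUVR decline in a 4-voxel-radius ball is detected at
corrected p < .05 in essentially every seed.

## Cohort statistics

2×2 tables use Pearson chi-square without continuity correction — the
convention that reproduces both printed p-values of the emulated study
from its printed counts (conversion 13/24 vs 9/24 → one-tailed
p = 0.1233; sex 18/6 vs 16/8 → p = 0.525). One-tailed p is half the
two-sided p when the observed effect lies in the tested direction,
`1 − p/2` otherwise. Survival uses lifelines: Kaplan–Meier per group
(Greenwood-based intervals, lifelines' exponential log(−log)
formulation) and the Fleming–Harrington weighted log-rank with weights
`S(t⁻)^p (1 − S(t⁻))^q` on the pooled Kaplan–Meier left limit. The
weight exponents behind the emulated study's p = .17 are unknown; the
default here is p = 1, q = 0 (early-difference weighting),
configurable, and no attempt is made to match that value. The
implementation agrees with a direct summation oracle of the weighted
score and variance to 1e-8, and reduces exactly to the log-rank test
at p = q = 0.

## PVC sensitivity experiment

The emulated study's qualitative claim is that small-region effects
(superior frontal, amygdala) reach significance only after PVC, with
non-PVC p-values just above threshold (.065, .094 vs .03, .02). The
experiment reproduces the *regime*, not the exact regions: a fixed
atlas (28×32×28, 10 regions), 12 subjects per group, visits 0–72 by
12 months, a carrier-vs-non-carrier slope difference of −2.6e-4
SUVR/month confined to the two small regions (amygdala, caudate; all
large regions share a common decline), between-subject slope sd
2e-4, atrophy 0.003/month on the small regions, and the random-slope
regional model. These sizes were fixed by a pre-hoc power analysis
targeting marginal significance: blur attenuates a small region's
group contrast by ~0.5 while replacing part of its between-subject
variability with neighbours', so the non-PVC z sits ~10–30 % below the
PVC z and detection straddles the .05 threshold. The assessed outcomes
are (a) non-PVC flags are a subset of PVC flags in the majority of
replicates and (b) PVC never flags fewer small regions in total. A
side observation worth flagging: without PVC, spill-in from declining
neighbours can produce *spurious* interactions in null regions (the
analysis run shows a false "prefrontal" flag in the non-PVC arm only)
— partial volume correction removes bias as well as restoring
sensitivity.

## Interfaces and problem sizes

The analysis is driven by the numbered scripts under `analysis/` and
by `run_pipeline(PipelineConfig)`, which executes simulate → (PVC) →
SUVR → regional models → voxelwise inference → survival and writes
CSV/JSON tables plus a manifest; identical config and seed give
byte-identical outputs (per-image seeds derive from the master seed
via `SeedSequence`). The functions and scripts *are* the command-line
surface; no separate console entry point is shipped. Default problem
sizes (40×48×40 grid at 1.5 mm, 16³ calibration grids, 200-replicate
calibrations, 6-replicate sensitivity runs) are desk-scale choices
that keep every experiment's statistical question answerable in
minutes on one core; all are parameters, so larger runs need only a
config change.

## Known limitations

* Atlas geometry is non-anatomical; regional adjacency (which drives
  spill-in) differs from real brains.
* The mixed model assumes linear trajectories and Gaussian errors —
  true by construction in the phantom, an approximation on real data.
* Wald z p-values are asymptotic; at 48 subjects they calibrate well
  (verified), but small-cohort use would warrant degrees-of-freedom
  corrections the emulated analysis did not specify.
* The permutation test assumes exchangeable sign-symmetric pair
  differences; systematic scanner drift between visits would violate
  this for real data.
* No multiple-testing correction across the regional models, by
  design fidelity.
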