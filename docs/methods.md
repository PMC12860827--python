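# Methods

## Problem and model

Chronic suppurative airway disease — here primary ciliary dyskinesia
(PCD) — produces both structural lung damage and active neutrophilic
inflammation. `petmiv` implements a quantification pipeline for
[18F]FDG PET of the lung acquired without attenuation correction (NAC),
together with the structural-scoring and statistical machinery needed to
relate metabolic, radiological and spirometric measures in a small
cohort.

NAC PET voxel values are relative: attenuation maps derived from MR
segmentation are unreliable in lung tissue, so absolute quantification
is not attempted. Instead the pipeline performs an internal
normalization. Given a PET volume $P$ and a reference region $R$ (a lung
area unaffected by disease, typically apical, supplied as a mask — it is
a reader's judgement, not an algorithm), the parametric image is

$$ Q(v) \;=\; \frac{P(v)}{\overline{P}_R}, \qquad
   \overline{P}_R = \frac{1}{|R|}\sum_{v\in R} P(v). $$

$Q$ is dimensionless, averages 1 over $R$ by construction, and is
invariant under any rescaling of the raw data — the property that makes
NAC data usable at all.

The volume of interest is a fixed threshold on $Q$ inside the segmented
lung field $L$, optionally minus exclusion regions $E$ (cardiac or
brown-fat uptake):

$$ \mathrm{VOI} = \{\, v \in L \setminus E : Q(v) \ge k \,\},
   \qquad k = 2 \text{ by default.} $$

From the VOI the metric suite is

* $\mathrm{MIV} = |\mathrm{VOI}| \cdot v_{\mathrm{cm}^3}$ (Metabolic
  Inflammatory Volume, the inflammatory analogue of oncology's metabolic
  tumor volume; $v_{\mathrm{cm}^3}$ = voxel volume),
* $\mathrm{MIV\%} = 100\,|\mathrm{VOI}|/|L|$,
* $\mathrm{SUV_{max}}, \mathrm{SUV_{mean}}$ = max/mean standardized
  uptake value over the VOI,
* $\mathrm{TLG} = \mathrm{MIV}\times\mathrm{SUV_{mean}}$.

Structural readings use a lobar extent score: six regions (five lobes +
lingula) × four features (bronchiectasis, consolidation, mucus plugging,
tree-in-bud), each graded 0 / 1 / 2 (absent / ≤ 50 % / > 50 % of the
lobe); feature, region and total scores are sums of grades (maximum 48).
The statistics battery comprises Bland–Altman agreement, unweighted
Cohen's kappa, ICC(2,1), Spearman correlation with Fisher-z CI, and
Mann–Whitney / Kruskal–Wallis comparisons.

## Numerical and design choices

**Threshold boundary.** VOI membership uses `>=` so that a voxel at
exactly twice the reference mean is included; the inclusive rule makes
the boundary case deterministic and matches common fixed-threshold
metabolic-volume practice.

**Single grid, no resampling.** All volumes are compared on the PET
voxel grid; shape mismatch or spacing disagreement beyond 1e-3 mm is an
error. Resampling/registration is out of scope — silent interpolation
would change metric values invisibly.

**Two scalings, kept separate.** The VOI always derives from the
parametric image; SUV statistics are read from a separately supplied
SUV-scaled volume (body-weight SUV with dose decay-corrected to scan
time, F-18 half-life 109.77 min by default). When no injection record is
available, SUV statistics are computed on raw values and flagged
`suv_scaled=False` rather than silently relabelled. `SUVmean` is
computed over the same 2×-threshold VOI (documented choice; readers
could in principle use a different region).

**Connected components.** No component filtering by default (pure
thresholding); an optional `min_component_voxels` filter uses
26-connectivity, stated explicitly for reproducibility.

**Kappa on presence.** The pipeline's per-feature HRCT-vs-MR kappa is
computed on dichotomized presence/absence. When a feature is present on
every scan for both modalities, chance agreement is 1 and kappa is
reported as *undefined* (flagged), never as a number.

**ICC form.** "ICC" alone is ambiguous; the package fixes ICC(2,1) —
two-way random effects, absolute agreement, single measure — the
standard form for inter-reader agreement on a continuous volume, with
the F-based 95 % CI (computed via pingouin). A hand ANOVA-mean-square
oracle cross-checks the point estimate in the test suite. All-identical
input has no ANOVA decomposition and returns a flagged NaN.

**Spearman CI.** 95 % CI by Fisher z with standard error
$1.03/\sqrt{n-3}$ (Fieller–Hartley–Pearson adjustment for rank
correlations). The method label is embedded in every result because CI
conventions differ across software. At $|\rho| = 1$ the interval
degenerates to the point estimate.

**Mann–Whitney p-values.** Exact for combined $n \le 20$ without ties,
otherwise normal approximation with continuity correction;
Kruskal–Wallis uses the tie-corrected H with the chi-square
approximation.

**Missing data.** Pairwise deletion per statistic; every result carries
its effective n. No multiple-testing correction by default (single
pre-specified α = 0.05 battery); an optional Benjamini–Hochberg column
is available and explicitly labelled as an extension.

## Synthetic data

**Phantoms.** Two ellipsoidal lung fields scaled to the grid (default
64³ voxels at 2 mm — a deliberately small phantom, not an anatomical
atlas), homogeneous lung background (default 100 arbitrary units),
soft tissue outside the lung at 0.6× background, an apical cap (top
14 mm of the lung) as reference region, spherical lesions specified as
(center, radius, uptake multiplier ≥ 1), an optional cardiac hot spot
outside the lung to exercise exclusion masks, and Gaussian or Poisson
noise. Because lesions are multipliers of the background, the 2×
threshold maps analytically onto ground truth: at zero noise a lesion is
in the VOI iff its multiplier ≥ 2. Truth voxel counts use the
*voxel-center-inside-sphere* rule, computed from geometry only — never
from the noisy volume — so the truth table is identical across noise
seeds. Sphere-volume recovery is exact up to voxelization error
(bounded by the surface-voxel count × voxel volume).

**Cohorts.** A standard-normal latent severity $s_i$ drives every
per-(region, feature) pathology latent
$u = b_f + c_r + \lambda s + \tau\,\varepsilon$; each modality reads
every cell with its own noise (MR with a small negative shift, giving
the HRCT-vs-MR bias) and grades it through two fixed cutpoints. PET
metrics and spirometry are linked to the standardized continuous
pathology burden $T = \sum u$ through a Gaussian copula: a variable with
planted Spearman correlation $\rho$ uses latent Pearson correlation
$r = 2\sin(\pi\rho/6)$, making the planted rank correlation analytic.
Ordinal discretization plus reader noise attenuate the observed
score-vs-metric Spearman by a factor measured at ≈ 0.97 (n = 20 000), so
a planted 0.6 is recovered near 0.58.

Defaults (16 patients; λ = 0.8, cell noise 0.6, reader noise 0.35, MR
shift −0.12, cutpoints 0 / 1.15; planted ρ: MIV 0.70, SUVmean 0.60,
SUVmax 0.15, FVC −0.73, FEV1 −0.58, FEF25–75 −0.37; MIV lognormal with
median 10.5 cm³ and log-SD 3.2, smoothly squashed below the lung volume;
SUVmean 2 + lognormal; spirometry normal with means 85.5/75.6/64.6 and
SDs 16.6/18.4/25.5 %predicted; exacerbations Poisson(1.2); sputum
positivity 0.375) were calibrated once, numerically, so that study-scale
replicates reproduce the published summary envelopes (score and metric
medians/IQRs, lobar gradient with spared upper lobes, total-score bias
≈ 1) and the correlation sign pattern structure↑ ↔ MIV↑ ↔ FVC↓.
Exacerbations and sputum status are generated independent of severity —
the null the corresponding group comparisons probe.

What the generator does **not** emulate: PET physics (scatter, PSF,
reconstruction artifacts), anatomical realism, reader drift over time,
within-patient longitudinal structure, and any dependence of exacerbation
history on severity. Passing tests therefore demonstrate correctness of
the *computational pipeline* under known ground truth, not clinical
performance on real scans.

## Verification strategy and problem sizes

Every operation is checked against an independent naive oracle:
exhaustive per-voxel scans for VOI membership and metrics (100 random
phantoms up to 64³), brute-force geometric voxel tests for phantom
truth, and textbook-formula implementations (explicit loops) for every
statistic. Property tests cover scale invariance of the normalized
quantification, threshold monotonicity, the score double-counting
identity, kappa symmetry/relabel invariance, and Spearman invariance
under increasing transforms. Null calibration uses 1000 seeded
replicates at n = 8 + 8; planted-correlation recovery uses n = 500;
study-scale checks use n = 16 with 100 replicate seeds. These sizes keep
the full suite and the acceptance script in the seconds-to-minutes
range while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Reference-region choice is an input; a poor reference (e.g. one
  containing disease) silently biases every metric — only emptiness and
  non-positive means are detectable errors.
* NIfTI only; DICOM ingestion, µ-map handling and kinetic modelling are
  out of scope.
* The lognormal MIV tail is heavy; at n = 16 single replicates can land
  outside the published envelopes (by design — that is sampling
  variation, not a bug).
* Agreement between the package's Spearman CIs and published CIs cannot
  be asserted without the underlying raw data, since the CI method
  behind published values is generally unstated.
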