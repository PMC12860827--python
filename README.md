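# petmiv

Reference-normalized PET quantification of lung inflammation, lobar
structural scoring, and the agreement/correlation statistics that link
them — built for studies of chronic suppurative airway disease (e.g.
primary ciliary dyskinesia) where PET is acquired without attenuation
correction and only relative uptake is meaningful.

## What it computes

Non-attenuation-corrected (NAC) PET is normalized voxel-wise by the mean
uptake $\overline{P}_R$ of a disease-free reference lung region, giving a
dimensionless parametric image $Q = P/\overline{P}_R$. Thresholding $Q$
at twice the reference mean inside the segmented lung field defines the
volume of interest, from which the package reports:

| metric | definition |
| --- | --- |
| MIV | Metabolic Inflammatory Volume: VOI volume in cm³ |
| MIV% | $100\,\lvert\mathrm{VOI}\rvert/\lvert\mathrm{lung}\rvert$ |
| SUVmax, SUVmean | max / mean standardized uptake value over the VOI |
| TLG | Total Lesion Glycolysis: MIV × SUVmean |

Structural readings enter as lobar extent scores — six regions (five
lobes + lingula) × four features (bronchiectasis, consolidation, mucus
plugging, tree-in-bud), graded 0/1/2 — and the statistics module provides
Bland–Altman agreement, Cohen's kappa (with the undefined-when-saturated
contract), ICC(2,1) with F-based CI, Spearman correlation with Fisher-z
CI, and Mann–Whitney/Kruskal–Wallis comparisons. A synthetic-data module
generates PET phantoms with analytic ground truth and cohort tables with
planted rank correlations, so the entire pipeline is testable without any
scan data. See `docs/methods.md` for the model, parameter defaults and
their rationale.

## Worked example

```python
from petmiv import Lesion, PhantomSpec, generate_phantom, quantify_scan

spec = PhantomSpec(lesions=(Lesion(center_mm=(37.8, 63.0, 55.0),
                                   radius_mm=10.0, uptake_multiplier=3.0),))
phantom = generate_phantom(spec)
metrics, voi, parametric = quantify_scan(phantom.pet, phantom.lung,
                                         phantom.reference)
```

Running `python examples/quantify_phantom.py` prints:

```
reference mean (normalization divisor): 100.0
MIV      : 4.256 cm^3   (truth: 532 voxels x 0.008 cm^3 = 4.256)
MIV%     : 1.556 % of 273 cm^3 lung
SUVmax   : 300.0   SUVmean: 300.0 (raw units: no injection record supplied)
TLG      : 1276.80  (= MIV x SUVmean)
```

A 10 mm sphere planted at 3× the lung background on a 2 mm grid occupies
532 voxel centers, and the pipeline recovers exactly those voxels: the
lesion's parametric value is 3 ≥ 2, the background's is 1, so MIV equals
the analytic truth (532 × 0.008 cm³ = 4.256 cm³, vs. the ideal sphere
volume 4.19 cm³ — the difference is voxelization). SUV values are raw
activity units here because no injection record was supplied (flagged in
the output); pass an `InjectionRecord` to get body-weight SUV.

Other examples: `examples/score_sheets.py` (lobar scoring),
`examples/agreement_statistics.py` (the statistics battery),
`examples/cohort_analysis.py` (full 16-patient synthetic cohort
analysis). A thin CLI mirrors the library:

```bash
petmiv simulate out/ --seed 1          # phantom NIfTIs + cohort CSV
petmiv quantify --pet out/pet.nii.gz --lung out/lung.nii.gz \
                --reference out/reference.nii.gz
petmiv stats out/cohort.csv --out-dir analysis/
petmiv run-all results/ --seed 1       # seeded end-to-end run + report
```

## Cohort CSV schema

One row per patient: `patient_id`; 48 score cells named
`<modality>_<region>_<feature>` (modality `hrct`/`mr`, regions
`right_upper, middle, right_lower, left_upper, lingula, left_lower`,
grades 0/1/2); metrics `miv_cm3, miv_pct, suv_max, suv_mean, tlg`;
spirometry `fvc_pct_pred, fev1_pct_pred, fef2575_pct_pred`;
`exacerbations_last_year`; `sputum_positive` (0/1). Missing cells are
preserved and propagate by pairwise deletion; out-of-range grades,
duplicate ids and unknown columns are load errors.

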