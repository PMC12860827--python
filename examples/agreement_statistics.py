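"""The agreement/correlation battery on a small two-reader data set.

Shows Bland-Altman limits of agreement, Cohen's kappa (including the
undefined case when a feature is present on every scan), ICC(2,1) for a
continuous measurement read by two operators, and Spearman correlation
with its Fisher-z confidence interval.
"""

import numpy as np

from petmiv import bland_altman, cohens_kappa, icc_absolute_agreement, spearman_ci

rng = np.random.default_rng(0)

# Two modalities scoring the same 16 patients (total scores 0..48).
hrct = rng.integers(2, 20, 16).astype(float)
mr = hrct - rng.integers(0, 4, 16)  # MR reads slightly lower
ba = bland_altman(hrct, mr)
print(f"Bland-Altman: bias {ba.bias:.2f}, limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}], "
      f"{ba.outside_count}/{ba.n} points outside")

# Presence/absence agreement per feature.
kappa = cohens_kappa((hrct > 10).astype(int), (mr > 10).astype(int))
print(f"kappa (dichotomized): {kappa.kappa:.2f} (po={kappa.observed_agreement:.2f})")
saturated = cohens_kappa([1] * 16, [1] * 16)
print(f"kappa when the feature is present on every scan: defined={saturated.defined} "
      "(chance agreement = 1, kappa not calculable)")

# Two readers measuring a continuous volume (cm^3) on 16 subjects.
truth = rng.lognormal(2.3, 1.0, 16)
reads = truth[:, None] * rng.normal(1.0, 0.15, (16, 2))
icc = icc_absolute_agreement(reads)
print(f"ICC(2,1): {icc.icc:.2f} [95% CI {icc.ci_low:.2f} to {icc.ci_high:.2f}] "
      f"({icc.model})")

# Rank correlation between structural score and metabolic volume.
corr = spearman_ci(hrct, truth + 5 * (hrct - hrct.mean()))
print(f"Spearman: rho={corr.rho:.2f} [95% CI {corr.ci_low:.2f} to {corr.ci_high:.2f}], "
      f"p={corr.p_value:.3g}, n={corr.n}")
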