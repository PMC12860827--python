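"""Agreement and correlation statistics for small imaging cohorts.

The battery mirrors standard practice for method-comparison studies at
n ≈ 16: Bland–Altman limits of agreement between two raters/modalities,
unweighted Cohen's kappa on categorical ratings, two-way random-effects
intraclass correlation for inter-reader reliability of a continuous
measurement, Spearman rank correlation with a Fisher-z confidence
interval, and nonparametric group comparisons (Mann–Whitney,
Kruskal–Wallis).  Missing values are removed pairwise per statistic and
every result reports its effective n and a method label.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
adjusted column can be added downstream as an explicitly marked
extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatsError",
    "BlandAltmanResult",
    "KappaResult",
    "ICCResult",
    "CorrelationResult",
    "GroupTestResult",
    "bland_altman",
    "cohens_kappa",
    "icc_absolute_agreement",
    "spearman_ci",
    "group_compare",
    "pearson_for_spearman",
]


class StatsError(ValueError):
    """Invalid statistical input."""


def _paired_complete(a, b, min_n: int, what: str):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError(f"{what}: inputs must be 1D series of equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < min_n:
        raise StatsError(f"{what}: need at least {min_n} complete pairs, got {len(a)}")
    return a, b


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference (bias) and 1.96·SD limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    outside_count: int
    method: str = "Bland-Altman, limits = bias +/- 1.96 * sample SD (ddof=1)"


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired series.

    Differences are ``a - b``; bias is their mean and the limits of
    agreement are bias ± 1.96 × sample standard deviation (n−1
    denominator).  Pairs with a missing value in either series are
    dropped; at least two complete pairs are required.
    """
    a, b = _paired_complete(a, b, 2, "bland_altman")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    return BlandAltmanResult(bias, lo, hi, sd, len(d), outside)


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa with an explicit undefined flag.

    ``defined`` is False exactly when chance agreement equals 1 — i.e.
    both raters used a single (identical) category for every item, as
    when a feature is present on every scan — in which case kappa is not
    calculable and ``kappa`` is NaN.
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    defined: bool
    n: int
    method: str = "Cohen's kappa, unweighted"


def cohens_kappa(r1, r2, weights: str | None = None) -> KappaResult:
    """Cohen's kappa between two categorical rating series.

    ``weights`` may be ``None`` (default, unweighted), ``"linear"`` or
    ``"quadratic"`` for ordinal categories; the weighted forms are an
    optional extension, never the default.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise StatsError("cohens_kappa: inputs must be 1D series of equal length")
    keep = ~(pd.isna(r1) | pd.isna(r2))
    r1, r2 = r1[keep], r2[keep]
    n = len(r1)
    if n < 1:
        raise StatsError("cohens_kappa: need at least 1 complete pair")
    cats = np.unique(np.concatenate([r1, r2]))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for x, y in zip(r1, r2):
        table[idx[x], idx[y]] += 1
    p = table / n
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)

    if weights is None:
        w = np.eye(k)
    else:
        grid = np.arange(k, dtype=float)
        dist = np.abs(grid[:, None] - grid[None, :]) / max(k - 1, 1)
        if weights == "linear":
            w = 1.0 - dist
        elif weights == "quadratic":
            w = 1.0 - dist**2
        else:
            raise StatsError(f"unknown weights {weights!r}")
    po = float((w * p).sum())
    pe = float((w * np.outer(p1, p2)).sum())
    method = "Cohen's kappa, " + (weights or "unweighted")
    if np.isclose(pe, 1.0, atol=1e-12):
        return KappaResult(float("nan"), po, pe, defined=False, n=n, method=method)
    return KappaResult((po - pe) / (1.0 - pe), po, pe, defined=True, n=n, method=method)


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    model: str = "two-way random, absolute agreement, single measure (ICC2)"
    note: str = ""


def icc_absolute_agreement(ratings) -> ICCResult:
    """Inter-rater reliability of a continuous measurement.

    ``ratings`` is a subjects × raters matrix with no missing cells,
    at least 5 subjects and at least 2 raters.  The estimate is ICC(2,1)
    from the two-way ANOVA mean squares with the standard F-based 95%
    confidence interval.  Zero-variance (all-identical) input has no
    defined ANOVA decomposition; it is returned as ICC = NaN with an
    explanatory note rather than an error.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise StatsError("icc: ratings must be a 2D subjects x raters matrix")
    n, k = m.shape
    if n < 5:
        raise StatsError(f"icc: need at least 5 subjects, got {n}")
    if k < 2:
        raise StatsError(f"icc: need at least 2 raters, got {k}")
    if not np.isfinite(m).all():
        bad = int(np.size(m) - np.count_nonzero(np.isfinite(m)))
        raise StatsError(f"icc: {bad} missing/non-finite cell(s); complete data required")
    if np.allclose(m, m.flat[0]):
        return ICCResult(
            float("nan"), float("nan"), float("nan"), n, k,
            note="zero-variance input: ICC undefined",
        )
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    # single-measure absolute agreement (labelled ICC2 / ICC(A,1) depending
    # on pingouin version)
    label = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[label]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    note = ""
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        note = "degenerate F interval (e.g. zero residual variance)"
    return ICCResult(float(row["ICC"]), ci_low, ci_high, n, k, note=note)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with Fisher-z confidence interval."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    method: str = "Spearman rho; 95% CI via Fisher z, SE = 1.03/sqrt(n-3)"


def spearman_ci(x, y) -> CorrelationResult:
    """Spearman correlation (midranks for ties) with a 95% CI.

    The CI uses the Fisher z transform with standard error
    ``1.03/sqrt(n-3)`` (the Fieller–Hartley–Pearson adjustment for rank
    correlations).  Requires at least 4 complete pairs and nonzero
    variance in both series.
    """
    x, y = _paired_complete(x, y, 4, "spearman_ci")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("spearman_ci: zero variance in one of the series")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    n = len(x)
    se = 1.03 / math.sqrt(n - 3)
    if abs(rho) >= 1.0:  # atanh diverges; the CI degenerates to the point
        lo = hi = rho
    else:
        z = math.atanh(rho)
        lo, hi = math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se)
    return CorrelationResult(rho, float(p), lo, hi, n)


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    test: str
    group_sizes: tuple[int, ...]
    method: str = ""


def group_compare(values, groups, test: str) -> GroupTestResult:
    """Nonparametric comparison of a measurement across groups.

    ``test`` is ``"mann_whitney"`` (exactly 2 groups; exact p-value for
    combined n ≤ 20 without ties, otherwise normal approximation with
    continuity correction) or ``"kruskal_wallis"`` (≥ 2 groups,
    tie-corrected H with chi-square approximation).  Pairs with missing
    values are dropped; every group must remain nonempty.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise StatsError("group_compare: values and groups must be equal-length 1D")
    keep = np.isfinite(values) & ~pd.isna(groups)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples) or len(samples) < 2:
        raise StatsError("group_compare: need at least 2 nonempty groups")
    sizes = tuple(len(s) for s in samples)

    if test == "mann_whitney":
        if len(samples) != 2:
            raise StatsError(
                f"mann_whitney requires exactly 2 groups, got {len(samples)}"
            )
        n_tot = sum(sizes)
        has_ties = len(np.unique(values)) < n_tot
        method = "exact" if (n_tot <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method=method,
            use_continuity=True,
        )
        return GroupTestResult(
            float(res.statistic), float(res.pvalue), "mann_whitney", sizes,
            method=f"Mann-Whitney U, {method}",
        )
    if test == "kruskal_wallis":
        res = sps.kruskal(*samples)
        return GroupTestResult(
            float(res.statistic), float(res.pvalue), "kruskal_wallis", sizes,
            method="Kruskal-Wallis H, tie-corrected, chi-square approximation",
        )
    raise StatsError(f"unknown test {test!r}")


def pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman correlation
    is ``rho_s`` (inverse of rho_s = (6/pi)·asin(r/2))."""
    if not -1.0 <= rho_s <= 1.0:
        raise StatsError(f"rank correlation must be in [-1, 1], got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)
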