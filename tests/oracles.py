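"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops and textbook
formulas, sharing no code path with the package — so agreement with the
package is evidence, not tautology.
"""

from __future__ import annotations

import math


def oracle_quantify(pet, lung, reference, spacing, threshold_factor,
                    exclusions=None, suv=None):
    """Exhaustive single-voxel-at-a-time quantification.

    ``pet``/``suv`` are 3D arrays, masks are 3D 0/1 arrays.  Returns a dict
    with the reference mean, sorted VOI voxel list and the five metrics.
    """
    nx, ny, nz = pet.shape
    if suv is None:
        suv = pet
    ref_sum, ref_n = 0.0, 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if reference[i, j, k]:
                    ref_sum += float(pet[i, j, k])
                    ref_n += 1
    ref_mean = ref_sum / ref_n
    voi, lung_n = [], 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if lung[i, j, k]:
                    lung_n += 1
                    if exclusions is not None and exclusions[i, j, k]:
                        continue
                    if float(pet[i, j, k]) / ref_mean >= threshold_factor:
                        voi.append((i, j, k))
    vox_cm3 = spacing[0] * spacing[1] * spacing[2] / 1000.0
    n_voi = len(voi)
    miv = n_voi * vox_cm3
    miv_pct = 100.0 * n_voi / lung_n
    if n_voi == 0:
        return {"reference_mean": ref_mean, "voi": [], "miv_cm3": 0.0,
                "miv_pct": 0.0, "suv_max": 0.0, "suv_mean": 0.0, "tlg": 0.0}
    vals = [float(suv[i, j, k]) for (i, j, k) in voi]
    suv_mean = sum(vals) / n_voi
    suv_max = max(vals)
    return {"reference_mean": ref_mean, "voi": sorted(voi), "miv_cm3": miv,
            "miv_pct": miv_pct, "suv_max": suv_max, "suv_mean": suv_mean,
            "tlg": miv * suv_mean}


def oracle_sphere_voxels(shape, spacing, center, radius, lung):
    """Voxel-center-inside-sphere membership, restricted to the lung mask."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                dx = i * spacing[0] - center[0]
                dy = j * spacing[1] - center[1]
                dz = k * spacing[2] - center[2]
                if dx * dx + dy * dy + dz * dz <= radius * radius and lung[i, j, k]:
                    count += 1
    return count


# --------------------------------------------------------------------------
# statistics oracles (textbook formulas, explicit loops)
# --------------------------------------------------------------------------


def midranks(x):
    n = len(x)
    order = sorted(range(n), key=lambda i: x[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def oracle_kappa(r1, r2):
    """(po, pe, kappa or None when pe == 1) from explicit contingency counts."""
    cats = sorted(set(list(r1) + list(r2)))
    n = len(r1)
    agree = sum(1 for a, b in zip(r1, r2) if a == b)
    po = agree / n
    pe = 0.0
    for c in cats:
        p1 = sum(1 for a in r1 if a == c) / n
        p2 = sum(1 for b in r2 if b == c) / n
        pe += p1 * p2
    if abs(pe - 1.0) < 1e-12:
        return po, pe, None
    return po, pe, (po - pe) / (1.0 - pe)


def oracle_bland_altman(a, b):
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def oracle_mannwhitney_u(a, b):
    """U for sample a via direct pair counting (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def oracle_mw_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration (tiny n only)."""
    from itertools import combinations

    pooled = list(a) + list(b)
    na = len(a)
    u_obs = oracle_mannwhitney_u(a, b)
    mean_u = na * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = oracle_mannwhitney_u(ga, gb)
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def oracle_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from rank sums."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        rsum = sum(ranks[pos:pos + len(g)])
        h += rsum * rsum / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = sum(t**3 - t for t in Counter(pooled).values())
    return h / (1.0 - ties / (n**3 - n))


def oracle_icc2_point(matrix):
    """ICC(2,1) point estimate from two-way ANOVA mean squares."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    row_means = [sum(row) / k for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def oracle_fisher_ci(rho, n):
    z = math.atanh(rho)
    se = 1.03 / math.sqrt(n - 3)
    return math.tanh(z - 1.96 * se), math.tanh(z + 1.96 * se)
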