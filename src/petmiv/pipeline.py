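"""Batch quantification and cohort-level analysis.

`run_quantification` maps the single-scan quantifier over a batch,
isolating per-scan failures.  `run_cohort_analysis` produces the result
surfaces of a method-comparison study on a joined cohort table:

* per-lobe-group and total score summaries per modality (medians, IQR)
  with a Kruskal–Wallis comparison across lobe groups;
* PET metric summaries (median, IQR);
* HRCT-vs-MR agreement: Bland–Altman per feature and for the total
  score, and Cohen's kappa per feature on dichotomized presence/absence
  (undefined — and flagged so — when a feature is present on every scan
  for both modalities);
* the full Spearman grid: scores × PET metrics, and scores + metrics ×
  spirometry, each with Fisher-z CI and effective n;
* Mann–Whitney comparisons of metrics and scores by exacerbation group
  (≥ 2 vs ≤ 1 in the past year) and sputum-culture status.

Statistics that cannot be computed (too few complete cases, zero
variance) are reported as ``not_computable`` rows with the reason; the
run never aborts on a single degenerate cell.  No multiple-testing
correction is applied by default; an optional Benjamini–Hochberg column
can be switched on as an explicitly marked extension.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import METRIC_COLUMNS, SPIROMETRY_COLUMNS, CohortTable
from .quant import quantify_scan
from .scores import DEFAULT_FEATURES, LOBE_GROUPS, MODALITIES
from .stats import (
    StatsError,
    bland_altman,
    cohens_kappa,
    group_compare,
    spearman_ci,
)
from .volumes import InjectionRecord, MaskVolume, ScalarVolume

__all__ = [
    "PipelineConfig",
    "ScanInput",
    "run_quantification",
    "run_cohort_analysis",
    "CohortAnalysis",
    "write_analysis",
    "run_all",
]

log = logging.getLogger("petmiv")

METRIC_LABELS = {
    "miv_cm3": "MIV (cm3)",
    "miv_pct": "MIV %",
    "suv_max": "SUV max",
    "suv_mean": "SUV mean",
    "tlg": "TLG",
}


@dataclass(frozen=True)
class PipelineConfig:
    """One artifact that fully describes a run."""

    threshold_factor: float = 2.0
    min_component_voxels: int = 0
    features: tuple[str, ...] = DEFAULT_FEATURES
    seed: int = 0
    n_patients: int = 16
    n_phantoms: int = 3
    bh_adjust: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        raw["features"] = tuple(raw.get("features", DEFAULT_FEATURES))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = list(self.features)
        return d


@dataclass(frozen=True)
class ScanInput:
    """One scan's volumes, already on a common grid."""

    scan_id: str
    pet: ScalarVolume
    lung: MaskVolume
    reference: MaskVolume
    exclusions: MaskVolume | None = None
    injection: InjectionRecord | None = None


def run_quantification(
    scans, config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify a batch of scans; failures are isolated, not batch-fatal.

    Returns a metrics table (one row per successful scan) and a list of
    failure records ``{"scan_id", "error"}``.
    """
    rows, failures = [], []
    for scan in scans:
        try:
            metrics, voi, parametric = quantify_scan(
                scan.pet,
                scan.lung,
                scan.reference,
                exclusions=scan.exclusions,
                threshold_factor=config.threshold_factor,
                min_component_voxels=config.min_component_voxels,
                injection=scan.injection,
            )
        except Exception as exc:
            log.warning("scan %s failed: %s", scan.scan_id, exc)
            failures.append({"scan_id": scan.scan_id, "error": str(exc)})
            continue
        row = {"scan_id": scan.scan_id, **metrics.as_dict()}
        row["lung_volume_cm3"] = scan.lung.volume_cm3
        rows.append(row)
    cols = [
        "scan_id", "miv_cm3", "miv_pct", "suv_max", "suv_mean", "tlg",
        "threshold_factor", "voi_voxel_count", "empty_voi", "suv_scaled",
        "lung_volume_cm3",
    ]
    return pd.DataFrame(rows, columns=cols), failures


# --------------------------------------------------------------------------
# Cohort analysis
# --------------------------------------------------------------------------


@dataclass
class CohortAnalysis:
    score_summary: pd.DataFrame
    lobe_summary: pd.DataFrame
    lobe_tests: pd.DataFrame
    metric_summary: pd.DataFrame
    agreement: pd.DataFrame
    correlations: pd.DataFrame
    group_tests: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "score_summary": self.score_summary,
            "lobe_summary": self.lobe_summary,
            "lobe_tests": self.lobe_tests,
            "metric_summary": self.metric_summary,
            "agreement": self.agreement,
            "correlations": self.correlations,
            "group_tests": self.group_tests,
        }


def _median_iqr(x: pd.Series) -> dict:
    x = x.dropna()
    if x.empty:
        return {"median": np.nan, "q1": np.nan, "q3": np.nan, "n": 0}
    return {
        "median": float(x.median()),
        "q1": float(x.quantile(0.25)),
        "q3": float(x.quantile(0.75)),
        "n": int(x.size),
    }


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (optional extension)."""
    p = p.astype(float)
    ok = p.notna()
    m = int(ok.sum())
    out = pd.Series(np.nan, index=p.index)
    if m == 0:
        return out
    vals = p[ok].sort_values()
    adj = vals.values * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out.loc[vals.index] = np.clip(adj, 0, 1)
    return out


def run_cohort_analysis(
    cohort: CohortTable, config: PipelineConfig = PipelineConfig()
) -> CohortAnalysis:
    """Compute all cohort-level result surfaces from a joined table."""
    d = cohort.data
    features = cohort.features

    # --- score summaries (per feature + total, per modality) -------------
    rows = []
    for modality in MODALITIES:
        for feat in features:
            rows.append(
                {"modality": modality, "score": feat,
                 **_median_iqr(cohort.feature_scores(modality, feat))}
            )
        rows.append(
            {"modality": modality, "score": "total",
             **_median_iqr(cohort.total_scores(modality))}
        )
    score_summary = pd.DataFrame(rows)

    # --- per-lobe-group summary + Kruskal-Wallis across groups -----------
    rows, tests = [], []
    for modality in MODALITIES:
        pooled_vals, pooled_groups = [], []
        for group, regions in LOBE_GROUPS.items():
            vals = pd.concat(
                [cohort.region_scores(modality, r) for r in regions],
                ignore_index=True,
            )
            rows.append({"modality": modality, "lobe_group": group, **_median_iqr(vals)})
            pooled_vals.append(vals)
            pooled_groups.append(pd.Series([group] * len(vals)))
        values = pd.concat(pooled_vals, ignore_index=True)
        groups = pd.concat(pooled_groups, ignore_index=True)
        try:
            res = group_compare(values, groups, "kruskal_wallis")
            tests.append(
                {"modality": modality, "test": res.test, "statistic": res.statistic,
                 "p_value": res.p_value, "n": int(sum(res.group_sizes)),
                 "method": res.method, "status": "ok"}
            )
        except (StatsError, ValueError) as exc:
            tests.append(
                {"modality": modality, "test": "kruskal_wallis",
                 "statistic": np.nan, "p_value": np.nan, "n": 0,
                 "method": "", "status": f"not_computable: {exc}"}
            )
    lobe_summary = pd.DataFrame(rows)
    lobe_tests = pd.DataFrame(tests)

    # --- PET metric summary ----------------------------------------------
    metric_summary = pd.DataFrame(
        [{"metric": METRIC_LABELS[m], **_median_iqr(d[m])} for m in METRIC_COLUMNS]
    )

    # --- HRCT vs MR agreement --------------------------------------------
    rows = []
    pairs = [(f, cohort.feature_scores("HRCT", f), cohort.feature_scores("MR", f))
             for f in features]
    pairs.append(("total", cohort.total_scores("HRCT"), cohort.total_scores("MR")))
    for name, a, b in pairs:
        try:
            ba = bland_altman(a, b)
            rows.append(
                {"score": name, "statistic": "bland_altman", "estimate": ba.bias,
                 "ci_low": ba.loa_low, "ci_high": ba.loa_high, "p_value": np.nan,
                 "n": ba.n, "method": ba.method, "status": "ok"}
            )
        except StatsError as exc:
            rows.append(
                {"score": name, "statistic": "bland_altman", "estimate": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "n": 0,
                 "method": "", "status": f"not_computable: {exc}"}
            )
    for feat in features:
        # presence/absence agreement, as read for a feature that may
        # saturate (kappa undefined when every scan shows the feature)
        a = (cohort.feature_scores("HRCT", feat) > 0).astype(float)
        b = (cohort.feature_scores("MR", feat) > 0).astype(float)
        keep = cohort.feature_scores("HRCT", feat).notna() & cohort.feature_scores(
            "MR", feat
        ).notna()
        try:
            kr = cohens_kappa(a[keep], b[keep])
            status = "ok" if kr.defined else "undefined: single shared category"
            rows.append(
                {"score": feat, "statistic": "kappa_presence", "estimate": kr.kappa,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                 "n": kr.n, "method": kr.method, "status": status}
            )
        except StatsError as exc:
            rows.append(
                {"score": feat, "statistic": "kappa_presence", "estimate": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "n": 0,
                 "method": "", "status": f"not_computable: {exc}"}
            )
    agreement = pd.DataFrame(rows)

    # --- Spearman grid -----------------------------------------------------
    score_vars: dict[str, pd.Series] = {}
    for modality in MODALITIES:
        for feat in features:
            score_vars[f"{modality.lower()}_{feat}"] = cohort.feature_scores(
                modality, feat
            )
        score_vars[f"{modality.lower()}_total"] = cohort.total_scores(modality)
    metric_vars = {m: d[m] for m in METRIC_COLUMNS}
    spiro_vars = {sp: d[sp] for sp in SPIROMETRY_COLUMNS}

    grid_pairs = [
        (sname, mname, s, m)
        for sname, s in score_vars.items()
        for mname, m in metric_vars.items()
    ]
    grid_pairs += [
        (vname, spname, v, sp)
        for vname, v in {**score_vars, **metric_vars}.items()
        for spname, sp in spiro_vars.items()
    ]
    rows = []
    for xname, yname, x, y in grid_pairs:
        try:
            c = spearman_ci(x, y)
            rows.append(
                {"x": xname, "y": yname, "rho": c.rho, "p_value": c.p_value,
                 "ci_low": c.ci_low, "ci_high": c.ci_high, "n": c.n,
                 "method": c.method, "status": "ok"}
            )
        except StatsError as exc:
            rows.append(
                {"x": xname, "y": yname, "rho": np.nan, "p_value": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "n": 0, "method": "",
                 "status": f"not_computable: {exc}"}
            )
    correlations = pd.DataFrame(rows)
    if config.bh_adjust:
        correlations["p_bh_adjusted_extension"] = _bh_adjust(correlations["p_value"])

    # --- group comparisons --------------------------------------------------
    exac = d["exacerbations_last_year"]
    groupings = {
        "exacerbations_ge2": exac.map(
            lambda v: np.nan if pd.isna(v) else ("ge2" if v >= 2 else "le1")
        ),
        "sputum_positive": d["sputum_positive"].map(
            lambda v: np.nan if pd.isna(v) else ("positive" if v > 0 else "negative")
        ),
    }
    outcome_vars = {
        **{m: d[m] for m in METRIC_COLUMNS},
        "hrct_total": cohort.total_scores("HRCT"),
        "mr_total": cohort.total_scores("MR"),
    }
    rows = []
    for gname, glabels in groupings.items():
        for vname, vals in outcome_vars.items():
            try:
                res = group_compare(vals, glabels, "mann_whitney")
                rows.append(
                    {"grouping": gname, "variable": vname, "test": res.test,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n": int(sum(res.group_sizes)),
                     "group_sizes": "/".join(map(str, res.group_sizes)),
                     "method": res.method, "status": "ok"}
                )
            except (StatsError, ValueError) as exc:
                rows.append(
                    {"grouping": gname, "variable": vname, "test": "mann_whitney",
                     "statistic": np.nan, "p_value": np.nan, "n": 0,
                     "group_sizes": "", "method": "",
                     "status": f"not_computable: {exc}"}
                )
    group_tests = pd.DataFrame(rows)

    return CohortAnalysis(
        score_summary, lobe_summary, lobe_tests, metric_summary,
        agreement, correlations, group_tests,
    )


# --------------------------------------------------------------------------
# run-all orchestration
# --------------------------------------------------------------------------


def write_analysis(analysis: CohortAnalysis, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in analysis.tables().items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    return paths


def _report(config: PipelineConfig, metrics: pd.DataFrame, failures: list,
            analysis: CohortAnalysis) -> str:
    lines = ["# petmiv run report", ""]
    lines.append("## Configuration")
    lines.append("```json")
    lines.append(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    lines.append("```")
    lines.append("")
    lines.append(f"## Scan quantification: {len(metrics)} scan(s), "
                 f"{len(failures)} failure(s)")
    if len(metrics):
        lines.append(metrics.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    for f in failures:
        lines.append(f"- FAILED {f['scan_id']}: {f['error']}")
    lines.append("")
    for name, df in analysis.tables().items():
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    return "\n".join(lines) + "\n"


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Simulate, quantify and analyze, writing all outputs under ``out_dir``.

    The result bundle is a pure function of the config (including its
    seed): re-running with the same config writes byte-identical CSVs.
    Returns a summary dict with output paths and the failure count.
    """
    from .phantom import CohortSpec, PhantomSpec, Lesion, generate_cohort, generate_phantom

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # A small phantom batch exercising detectable / sub-threshold /
    # lesion-free scans.
    scans = []
    lesion_sets = [
        (Lesion((37.8, 63.0, 55.0), 10.0, 3.0),),
        (Lesion((88.2, 63.0, 55.0), 8.0, 1.9),),
        (),
    ]
    for i in range(config.n_phantoms):
        spec = PhantomSpec(
            lesions=lesion_sets[i % len(lesion_sets)],
            noise="gaussian",
            seed=int(rng.integers(2**31)),
        )
        ph = generate_phantom(spec)
        scans.append(
            ScanInput(f"phantom{i + 1:02d}", ph.pet, ph.lung, ph.reference,
                      exclusions=ph.exclusions)
        )
    metrics, failures = run_quantification(scans, config)
    metrics_path = out_dir / "phantom_metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.10g")

    cohort = generate_cohort(
        CohortSpec(n_patients=config.n_patients, seed=config.seed,
                   features=config.features)
    )
    cohort_path = out_dir / "cohort.csv"
    cohort.data.to_csv(cohort_path, index=False)

    analysis = run_cohort_analysis(cohort, config)
    paths = write_analysis(analysis, out_dir)

    report_path = out_dir / "report.md"
    report_path.write_text(_report(config, metrics, failures, analysis))

    return {
        "out_dir": str(out_dir),
        "metrics_csv": str(metrics_path),
        "cohort_csv": str(cohort_path),
        "analysis_csvs": [str(p) for p in paths],
        "report": str(report_path),
        "n_scan_failures": len(failures),
    }
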