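"""Synthetic phantoms and cohorts with known ground truth.

Two generators make every pipeline stage testable without any scan data:

* :func:`generate_phantom` builds a chest-like PET volume — two
  ellipsoidal lung fields with a homogeneous background, an unaffected
  apical cap designated as the reference region, spherical lesions with
  specified uptake multipliers, an optional cardiac hot spot outside the
  lung to exercise exclusion masks, and optional Gaussian or Poisson
  noise.  Ground truth (each lesion's in-lung voxel count) is computed
  analytically from the geometry, never from the noisy volume, using the
  voxel-center-inside-sphere membership rule.  Because lesion uptake is
  specified as a multiplier of the lung background, the default 2×
  parametric threshold maps directly onto truth: at zero noise a lesion
  is detected iff its multiplier is ≥ the threshold factor.

* :func:`generate_cohort` builds a per-patient table with planted
  monotone structure: a latent severity drives ordinal lobar scores
  (thresholded Gaussian cells with reader noise, one reading per
  modality), while PET metrics and spirometry are linked to the
  continuous pathology burden through a Gaussian copula, so the planted
  Spearman correlations are analytic (Pearson latent correlation
  r = 2·sin(π·ρ/6)).  Defaults emulate a 16-patient cohort with the
  published summary envelopes and correlation sign pattern
  (structure↑ ↔ MIV↑ ↔ FVC↓).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable, cohort_columns
from .scores import DEFAULT_FEATURES, LOBE_GROUPS, MODALITIES, REGIONS, score_column
from .stats import pearson_for_spearman
from .volumes import MaskVolume, ScalarVolume

__all__ = [
    "PhantomError",
    "Lesion",
    "PhantomSpec",
    "PhantomResult",
    "LesionTruth",
    "generate_phantom",
    "random_phantom_spec",
    "CohortSpec",
    "generate_cohort",
]


class PhantomError(ValueError):
    """Invalid phantom or cohort specification."""


# --------------------------------------------------------------------------
# PET phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion: center (mm), radius (mm), uptake multiplier ≥ 1
    relative to the lung background."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake_multiplier: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise PhantomError(f"lesion radius must be > 0, got {self.radius_mm}")
        if self.uptake_multiplier < 1:
            raise PhantomError(
                f"uptake multiplier must be >= 1, got {self.uptake_multiplier}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and noise description of one synthetic scan.

    The lung field is two ellipsoids whose size scales with the grid; the
    reference region is an apical cap of thickness ``reference_cap_mm``.
    ``noise`` is ``"none"``, ``"gaussian"`` (additive, SD =
    ``gaussian_sd_rel`` × background) or ``"poisson"`` (voxel counts drawn
    as Poisson(value × ``poisson_scale``) / scale).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesions: tuple[Lesion, ...] = ()
    background_activity: float = 100.0
    soft_tissue_fraction: float = 0.6
    reference_cap_mm: float = 14.0
    noise: str = "none"
    gaussian_sd_rel: float = 0.05
    poisson_scale: float = 5.0
    cardiac_hotspot: bool = False
    hotspot_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise PhantomError(f"shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacing must be positive, got {self.spacing}")
        if self.background_activity <= 0:
            raise PhantomError("background_activity must be > 0")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise PhantomError(f"unknown noise model {self.noise!r}")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass(frozen=True)
class LesionTruth:
    """Analytic ground truth for one lesion (noise-independent)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake_multiplier: float
    voxel_count: int  # voxel centers inside the sphere AND inside the lung
    volume_cm3: float

    def detectable(self, threshold_factor: float = 2.0) -> bool:
        return self.uptake_multiplier >= threshold_factor


@dataclass(frozen=True)
class PhantomResult:
    pet: ScalarVolume
    lung: MaskVolume
    reference: MaskVolume
    exclusions: MaskVolume
    truth: tuple[LesionTruth, ...]
    spec: PhantomSpec
    _lesion_voxels: tuple[np.ndarray, ...]  # boolean in-lung membership per lesion

    def truth_voi_voxel_count(self, threshold_factor: float = 2.0) -> int:
        """Union in-lung voxel count of all lesions with multiplier ≥ factor."""
        sel = np.zeros(self.lung.shape, dtype=bool)
        for lesion, vox in zip(self.truth, self._lesion_voxels):
            if lesion.uptake_multiplier >= threshold_factor:
                sel |= vox
        return int(sel.sum())

    def truth_miv_cm3(self, threshold_factor: float = 2.0) -> float:
        return self.truth_voi_voxel_count(threshold_factor) * self.lung.voxel_volume_cm3


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, center, semi):
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _lung_geometry(shape, spacing):
    """Two ellipsoidal lung fields; returns (lung_mask, extents)."""
    xx, yy, zz = _voxel_centers(shape, spacing)
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))
    semi = (0.17 * ext[0], 0.24 * ext[1], 0.40 * ext[2])
    z_c = 0.48 * ext[2]
    right = _ellipsoid(xx, yy, zz, (0.30 * ext[0], 0.50 * ext[1], z_c), semi)
    left = _ellipsoid(xx, yy, zz, (0.70 * ext[0], 0.50 * ext[1], z_c), semi)
    return right | left, (xx, yy, zz), ext


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build a phantom scan and its analytic truth table.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`PhantomError` when a lesion extends outside the lung field or
    overlaps the reference region.
    """
    shape = tuple(int(s) for s in spec.shape)
    lung_sel, (xx, yy, zz), ext = _lung_geometry(shape, spec.spacing)
    if not lung_sel.any():
        raise PhantomError("degenerate geometry: empty lung field")

    # Apical reference cap: topmost slab of the lung field.
    z_top = zz[lung_sel].max()
    ref_sel = lung_sel & (zz >= z_top - spec.reference_cap_mm)

    lesion_voxels: list[np.ndarray] = []
    truths: list[LesionTruth] = []
    vox_cm3 = float(np.prod(spec.spacing)) / 1000.0
    for lesion in spec.lesions:
        cx, cy, cz = lesion.center_mm
        inside = (
            (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        ) <= lesion.radius_mm**2
        if np.any(inside & ~lung_sel):
            raise PhantomError(
                f"lesion at {lesion.center_mm} (r={lesion.radius_mm} mm) "
                "extends outside the lung field"
            )
        if np.any(inside & ref_sel):
            raise PhantomError(
                f"lesion at {lesion.center_mm} overlaps the reference region"
            )
        in_lung = inside & lung_sel
        truths.append(
            LesionTruth(
                lesion.center_mm,
                lesion.radius_mm,
                lesion.uptake_multiplier,
                int(in_lung.sum()),
                float(in_lung.sum()) * vox_cm3,
            )
        )
        lesion_voxels.append(in_lung)

    bg = spec.background_activity
    pet = np.where(lung_sel, bg, spec.soft_tissue_fraction * bg)
    # Overlapping lesions take the maximum multiplier.
    mult = np.ones(shape)
    for lesion, vox in zip(spec.lesions, lesion_voxels):
        mult[vox] = np.maximum(mult[vox], lesion.uptake_multiplier)
    pet = np.where(lung_sel, bg * mult, pet)

    excl_sel = np.zeros(shape, dtype=bool)
    if spec.cardiac_hotspot:
        heart = _ellipsoid(
            xx, yy, zz,
            (0.50 * ext[0], 0.55 * ext[1], 0.30 * ext[2]),
            (0.13 * ext[0], 0.12 * ext[1], 0.12 * ext[2]),
        )
        heart &= ~lung_sel  # non-specific uptake sits outside the lung field
        pet = np.where(heart, spec.hotspot_multiplier * bg, pet)
        excl_sel = heart

    if spec.noise == "gaussian":
        rng = np.random.default_rng(spec.seed)
        pet = pet + rng.normal(0.0, spec.gaussian_sd_rel * bg, size=shape)
        pet = np.maximum(pet, 0.0)
    elif spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        pet = rng.poisson(pet * spec.poisson_scale).astype(float) / spec.poisson_scale

    grid = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    return PhantomResult(
        pet=ScalarVolume(pet, **grid),
        lung=MaskVolume(lung_sel.astype(np.uint8), **grid),
        reference=MaskVolume(ref_sel.astype(np.uint8), **grid),
        exclusions=MaskVolume(excl_sel.astype(np.uint8), **grid),
        truth=tuple(truths),
        spec=spec,
        _lesion_voxels=tuple(lesion_voxels),
    )


def random_phantom_spec(rng: np.random.Generator, max_extent_voxels: int = 64) -> PhantomSpec:
    """Draw a random valid phantom spec (for randomized oracle testing).

    Shapes are ≤ ``max_extent_voxels`` per axis; lesions are placed inside
    the lung field away from the apical reference cap, with multipliers
    spanning both sides of the default 2× threshold.
    """
    shape = tuple(int(rng.integers(24, max_extent_voxels + 1)) for _ in range(3))
    spacing = tuple(float(rng.choice([1.5, 2.0, 2.5, 3.0])) for _ in range(3))
    spec = PhantomSpec(shape=shape, spacing=spacing, seed=int(rng.integers(2**31)))
    lung_sel, (xx, yy, zz), ext = _lung_geometry(shape, spacing)
    z_top = zz[lung_sel].max()
    usable = lung_sel & (zz < z_top - spec.reference_cap_mm)

    lesions: list[Lesion] = []
    n_target = int(rng.integers(0, 4))
    attempts = 0
    idx = np.argwhere(usable)
    while len(lesions) < n_target and attempts < 60 and len(idx):
        attempts += 1
        i, j, k = idx[rng.integers(len(idx))]
        center = (float(xx[i, j, k]), float(yy[i, j, k]), float(zz[i, j, k]))
        radius = float(rng.uniform(4.0, 14.0))
        inside = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2) <= radius**2
        if np.any(inside & ~usable):
            continue
        mult = float(rng.uniform(1.2, 4.0))
        lesions.append(Lesion(center, radius, mult))
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        lesions=tuple(lesions),
        background_activity=float(rng.uniform(50.0, 200.0)),
        noise=str(rng.choice(["none", "gaussian"])),
        gaussian_sd_rel=0.05,
        cardiac_hotspot=bool(rng.integers(0, 2)),
        seed=int(rng.integers(2**31)),
    )


# --------------------------------------------------------------------------
# Synthetic cohorts
# --------------------------------------------------------------------------

# Calibrated once against the published 16-patient summary envelopes
# (per-feature and total score medians/IQRs, metric medians/IQRs,
# spirometry means/SDs) and the correlation sign pattern; see the methods
# note for the calibration procedure.
_REGION_EFFECTS = {
    "right_upper": -1.55,
    "left_upper": -1.55,
    "right_lower": 0.10,
    "left_lower": 0.10,
    "middle": 0.42,
    "lingula": 0.42,
}
_FEATURE_EFFECTS = {
    "bronchiectasis": 0.25,
    "consolidation": -0.36,
    "mucus_plugging": -0.36,
    "tree_in_bud": -0.60,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generating model for a synthetic cohort table.

    A standard-normal latent severity drives per-(region, feature)
    pathology latents ``u = b_f + c_r + λ·s + τ·ε``; each modality reads
    every cell with its own noise (and a small MR shift, giving the
    HRCT-vs-MR agreement structure) and grades it through two cutpoints.
    PET metrics and spirometry are tied to the standardized continuous
    pathology burden ``T = Σ u`` through a Gaussian copula, so each
    ``*_rho`` field is the planted population Spearman correlation
    between that variable and T.  Setting a rho to 0 severs the link
    (null case); the defaults carry the published sign pattern.
    """

    n_patients: int = 16
    seed: int = 0
    features: tuple[str, ...] = DEFAULT_FEATURES
    # ordinal score model
    severity_loading: float = 0.8
    cell_noise_sd: float = 0.6
    reader_noise_sd: float = 0.35
    mr_shift: float = -0.12
    cutpoints: tuple[float, float] = (0.0, 1.15)
    region_effects: dict = field(default_factory=lambda: dict(_REGION_EFFECTS))
    feature_effects: dict = field(default_factory=lambda: dict(_FEATURE_EFFECTS))
    # planted rank correlations with the pathology burden
    miv_rho: float = 0.70
    suv_mean_rho: float = 0.60
    suv_max_rho: float = 0.15
    fvc_rho: float = -0.73
    fev1_rho: float = -0.58
    fef2575_rho: float = -0.37
    # marginal distributions
    miv_log_median: float = math.log(10.5)
    miv_log_sigma: float = 3.2
    suv_mean_floor: float = 2.0
    suv_mean_log_mu: float = math.log(0.6)
    suv_mean_log_sigma: float = 1.0
    suv_max_ratio_log_mu: float = math.log(0.25)
    suv_max_ratio_log_sigma: float = 0.4
    lung_volume_mean_cm3: float = 2600.0
    lung_volume_sd_cm3: float = 350.0
    fvc_mean: float = 85.5
    fvc_sd: float = 16.6
    fev1_mean: float = 75.6
    fev1_sd: float = 18.4
    fef2575_mean: float = 64.6
    fef2575_sd: float = 25.5
    exacerbation_rate: float = 1.2
    sputum_positive_p: float = 0.375

    def __post_init__(self):
        if self.n_patients < 4:
            raise PhantomError(f"n_patients must be >= 4, got {self.n_patients}")
        for name in ("severity_loading", "cell_noise_sd", "reader_noise_sd"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")
        for name in (
            "miv_rho", "suv_mean_rho", "suv_max_rho",
            "fvc_rho", "fev1_rho", "fef2575_rho",
        ):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise PhantomError(f"{name} must be in [-1, 1]")
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise PhantomError("cutpoints must be increasing")
        missing = set(REGIONS) - set(self.region_effects)
        if missing:
            raise PhantomError(f"region_effects missing {sorted(missing)}")
        missing = set(self.features) - set(self.feature_effects)
        if missing:
            raise PhantomError(f"feature_effects missing {sorted(missing)}")


def _copula_draw(rng, t_star, rho_s, n):
    """Gaussian latent with planted Spearman correlation ``rho_s`` to t_star."""
    r = pearson_for_spearman(rho_s)
    return r * t_star + math.sqrt(1.0 - r * r) * rng.standard_normal(n)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Generate a validated cohort table with planted structure.

    Deterministic for a fixed ``spec.seed``.  The generating parameters
    (including every planted rank correlation) are embedded in
    ``CohortTable.params`` for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cells = [(r, f) for r in REGIONS for f in spec.features]
    n_cells = len(cells)

    s = rng.standard_normal(n)
    eps_cell = rng.standard_normal((n, n_cells))
    u = np.empty((n, n_cells))
    offsets = np.array(
        [spec.feature_effects[f] + spec.region_effects[r] for r, f in cells]
    )
    u = offsets[None, :] + spec.severity_loading * s[:, None] + spec.cell_noise_sd * eps_cell

    # Standardized continuous pathology burden (analytic moments).
    t_raw = u.sum(axis=1)
    t_mean = offsets.sum()
    t_sd = math.sqrt(
        (n_cells * spec.severity_loading) ** 2 + n_cells * spec.cell_noise_sd**2
    )
    t_star = (t_raw - t_mean) / t_sd

    t1, t2 = spec.cutpoints
    grades = {}
    for modality in MODALITIES:
        shift = spec.mr_shift if modality == "MR" else 0.0
        x = u + shift + spec.reader_noise_sd * rng.standard_normal((n, n_cells))
        grades[modality] = (x > t1).astype(int) + (x > t2).astype(int)

    # PET metrics and spirometry via Gaussian copula links to t_star.
    z_miv = _copula_draw(rng, t_star, spec.miv_rho, n)
    z_suv = _copula_draw(rng, t_star, spec.suv_mean_rho, n)
    z_max = _copula_draw(rng, t_star, spec.suv_max_rho, n)
    z_fvc = _copula_draw(rng, t_star, spec.fvc_rho, n)
    z_fev1 = _copula_draw(rng, t_star, spec.fev1_rho, n)
    z_fef = _copula_draw(rng, t_star, spec.fef2575_rho, n)

    lung_vol = np.maximum(
        rng.normal(spec.lung_volume_mean_cm3, spec.lung_volume_sd_cm3, n), 1500.0
    )
    miv_raw = np.exp(spec.miv_log_median + spec.miv_log_sigma * z_miv)
    # Smooth monotone squash keeps MIV below the lung volume without rank ties.
    miv = lung_vol * (1.0 - np.exp(-miv_raw / lung_vol))
    miv_pct = 100.0 * miv / lung_vol
    suv_mean = spec.suv_mean_floor + np.exp(
        spec.suv_mean_log_mu + spec.suv_mean_log_sigma * z_suv
    )
    suv_max = suv_mean * (
        1.0 + np.exp(spec.suv_max_ratio_log_mu + spec.suv_max_ratio_log_sigma * z_max)
    )
    tlg = miv * suv_mean
    fvc = np.maximum(spec.fvc_mean + spec.fvc_sd * z_fvc, 15.0)
    fev1 = np.maximum(spec.fev1_mean + spec.fev1_sd * z_fev1, 15.0)
    fef = np.maximum(spec.fef2575_mean + spec.fef2575_sd * z_fef, 15.0)

    exac = rng.poisson(spec.exacerbation_rate, n)
    sputum = (rng.random(n) < spec.sputum_positive_p).astype(int)

    data = {"patient_id": [f"P{i + 1:03d}" for i in range(n)]}
    for modality in MODALITIES:
        g = grades[modality]
        for j, (region, feat) in enumerate(cells):
            data[score_column(modality, region, feat)] = g[:, j]
    data.update(
        miv_cm3=np.round(miv, 4),
        miv_pct=np.round(miv_pct, 4),
        suv_max=np.round(suv_max, 4),
        suv_mean=np.round(suv_mean, 4),
        tlg=np.round(tlg, 4),
        fvc_pct_pred=np.round(fvc, 2),
        fev1_pct_pred=np.round(fev1, 2),
        fef2575_pct_pred=np.round(fef, 2),
        exacerbations_last_year=exac,
        sputum_positive=sputum,
    )
    df = pd.DataFrame(data, columns=cohort_columns(spec.features))
    params = asdict(spec)
    return CohortTable(df, features=spec.features, params=params)
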