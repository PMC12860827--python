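"""Reference-normalized PET quantification of lung inflammation.

Non-attenuation-corrected (NAC) PET carries relative, not absolute,
activity values, so quantification starts from an internal normalization:
every voxel is divided by the mean uptake of a reference lung region
chosen to be unaffected by disease (typically apical).  The resulting
*parametric image* is dimensionless and, by construction, averages 1 over
the reference region.

The volume of interest (VOI) is then defined by a fixed threshold on the
parametric image — by default twice the reference mean — restricted to
the segmented lung field and optionally excluding regions of non-specific
uptake (heart, brown fat).  From the VOI the metric suite is computed:

* **MIV** (Metabolic Inflammatory Volume): VOI volume in cm³, the
  inflammatory analogue of oncology's Metabolic Tumor Volume;
* **MIV%**: MIV as a percentage of the segmented lung volume;
* **SUVmax / SUVmean**: max/mean standardized uptake value over the VOI;
* **TLG** (Total Lesion Glycolysis): MIV × SUVmean.

The VOI always comes from the parametric image; SUV statistics are read
from a separately supplied SUV-scaled volume so that the two scalings
stay independently auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes import (
    InjectionRecord,
    MaskVolume,
    ScalarVolume,
    VolumeError,
    require_same_grid,
)

__all__ = [
    "QuantError",
    "ParametricImage",
    "MetabolicMetrics",
    "reference_mean",
    "make_parametric",
    "extract_voi",
    "compute_metrics",
    "suv_scale",
    "quantify_scan",
]

DEFAULT_THRESHOLD_FACTOR = 2.0


class QuantError(ValueError):
    """Invalid quantification input."""


@dataclass(frozen=True)
class ParametricImage:
    """Reference-normalized PET image: voxel value = PET / reference mean."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    reference_mean: float

    def __post_init__(self):
        if not (np.isfinite(self.reference_mean) and self.reference_mean > 0):
            raise QuantError(f"reference_mean must be > 0, got {self.reference_mean}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def as_volume(self) -> ScalarVolume:
        return ScalarVolume(self.data, self.spacing, self.origin)


@dataclass(frozen=True)
class MetabolicMetrics:
    """Metric suite for one scan.

    ``suv_max``/``suv_mean``/``tlg`` are zero with ``empty_voi`` set when
    the VOI contains no voxels.  ``suv_scaled`` records whether the SUV
    statistics came from a calibrated SUV volume or from raw NAC values.
    """

    miv_cm3: float
    miv_pct: float
    suv_max: float
    suv_mean: float
    tlg: float
    threshold_factor: float
    voi_voxel_count: int
    empty_voi: bool
    suv_scaled: bool = True

    def as_dict(self) -> dict:
        return {
            "miv_cm3": self.miv_cm3,
            "miv_pct": self.miv_pct,
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "tlg": self.tlg,
            "threshold_factor": self.threshold_factor,
            "voi_voxel_count": self.voi_voxel_count,
            "empty_voi": self.empty_voi,
            "suv_scaled": self.suv_scaled,
        }


def reference_mean(pet: ScalarVolume, reference: MaskVolume) -> float:
    """Arithmetic mean of PET values over the reference region.

    Raises
    ------
    QuantError
        If the reference mask is empty, or the mean is not strictly
        positive (an invalid reference region for normalization).
    """
    require_same_grid(pet, reference, "PET vs reference mask")
    sel = reference.as_bool()
    n = int(sel.sum())
    if n == 0:
        raise QuantError("reference mask is empty")
    m = float(pet.data[sel].mean())
    if not (np.isfinite(m) and m > 0):
        raise QuantError(f"reference mean must be > 0 for normalization, got {m}")
    return m


def make_parametric(pet: ScalarVolume, reference: MaskVolume) -> ParametricImage:
    """Divide every voxel by the reference-region mean.

    The result is dimensionless; its mean over the reference mask is 1 to
    numerical precision, and it is invariant under rescaling of the raw
    PET values (the point of internal normalization of NAC data).
    """
    m = reference_mean(pet, reference)
    return ParametricImage(pet.data / m, pet.spacing, pet.origin, reference_mean=m)


def extract_voi(
    parametric: ParametricImage,
    lung: MaskVolume,
    exclusions: MaskVolume | None = None,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    min_component_voxels: int = 0,
) -> MaskVolume:
    """Threshold the parametric image inside the lung field.

    A voxel joins the VOI when it lies inside ``lung``, outside
    ``exclusions``, and its parametric value is **at least**
    ``threshold_factor`` (inclusive boundary, so the default 2.0 captures
    voxels at exactly twice the reference mean).  With
    ``min_component_voxels > 0``, 26-connected components smaller than
    that are removed; by default no component filtering is applied.
    """
    if not (np.isfinite(threshold_factor) and threshold_factor > 0):
        raise QuantError(f"threshold_factor must be > 0, got {threshold_factor}")
    require_same_grid(parametric, lung, "parametric image vs lung mask")
    if lung.voxel_count == 0:
        raise QuantError("lung mask is empty")
    sel = lung.as_bool() & (parametric.data >= threshold_factor)
    if exclusions is not None:
        require_same_grid(parametric, exclusions, "parametric image vs exclusion mask")
        sel &= ~exclusions.as_bool()
    if min_component_voxels > 0 and sel.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, n_comp = ndimage.label(sel, structure=structure)
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        sel &= ~np.isin(labels, small[small > 0])
    return MaskVolume(sel.astype(np.uint8), lung.spacing, lung.origin)


def compute_metrics(
    pet_suv: ScalarVolume,
    parametric: ParametricImage,
    voi: MaskVolume,
    lung: MaskVolume,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    suv_scaled: bool = True,
) -> MetabolicMetrics:
    """Compute MIV, MIV%, SUVmax, SUVmean and TLG for one scan.

    ``voi`` must be a subset of ``lung`` and all volumes must share one
    grid.  An empty VOI yields zero metrics with the ``empty_voi`` flag
    set rather than an error.
    """
    require_same_grid(pet_suv, parametric, "SUV volume vs parametric image")
    require_same_grid(pet_suv, voi, "SUV volume vs VOI")
    require_same_grid(pet_suv, lung, "SUV volume vs lung mask")
    voi_sel = voi.as_bool()
    if np.any(voi_sel & ~lung.as_bool()):
        raise QuantError("VOI is not a subset of the lung mask")
    n_lung = lung.voxel_count
    if n_lung == 0:
        raise QuantError("lung mask is empty")
    n_voi = int(voi_sel.sum())
    vox_cm3 = voi.voxel_volume_cm3
    miv = n_voi * vox_cm3
    miv_pct = 100.0 * n_voi / n_lung
    if n_voi == 0:
        return MetabolicMetrics(
            miv_cm3=0.0,
            miv_pct=0.0,
            suv_max=0.0,
            suv_mean=0.0,
            tlg=0.0,
            threshold_factor=threshold_factor,
            voi_voxel_count=0,
            empty_voi=True,
            suv_scaled=suv_scaled,
        )
    vals = pet_suv.data[voi_sel]
    suv_mean = float(vals.mean())
    suv_max = float(vals.max())
    return MetabolicMetrics(
        miv_cm3=miv,
        miv_pct=miv_pct,
        suv_max=suv_max,
        suv_mean=suv_mean,
        tlg=miv * suv_mean,
        threshold_factor=threshold_factor,
        voi_voxel_count=n_voi,
        empty_voi=False,
        suv_scaled=suv_scaled,
    )


def suv_scale(activity_volume: ScalarVolume, injection: InjectionRecord) -> ScalarVolume:
    """Body-weight SUV normalization of a calibrated activity volume.

    ``activity_volume`` is in kBq/mL.  Each voxel becomes
    ``activity × body_weight(g) / decay_corrected_dose(kBq)`` with the
    injected dose decayed to scan time over the injection-to-scan
    interval, assuming 1 g/mL tissue density.  A whole-body-uniform
    tracer distribution therefore maps to SUV = 1.
    """
    dose_kbq = injection.decay_corrected_dose_kbq
    weight_g = injection.body_weight_kg * 1000.0
    return activity_volume.with_data(activity_volume.data * (weight_g / dose_kbq))


def quantify_scan(
    pet: ScalarVolume,
    lung: MaskVolume,
    reference: MaskVolume,
    exclusions: MaskVolume | None = None,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    min_component_voxels: int = 0,
    injection: InjectionRecord | None = None,
) -> tuple[MetabolicMetrics, MaskVolume, ParametricImage]:
    """End-to-end quantification of one scan.

    Builds the parametric image, extracts the threshold VOI and computes
    the metric suite.  When an :class:`InjectionRecord` is supplied the
    PET volume is interpreted as calibrated activity (kBq/mL) and SUV
    statistics use the SUV-scaled volume; otherwise SUV statistics are
    computed on the raw values and flagged ``suv_scaled=False``.
    """
    parametric = make_parametric(pet, reference)
    voi = extract_voi(
        parametric,
        lung,
        exclusions=exclusions,
        threshold_factor=threshold_factor,
        min_component_voxels=min_component_voxels,
    )
    if injection is not None:
        suv_vol = suv_scale(pet, injection)
        scaled = True
    else:
        suv_vol = pet
        scaled = False
    metrics = compute_metrics(
        suv_vol, parametric, voi, lung, threshold_factor, suv_scaled=scaled
    )
    return metrics, voi, parametric
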