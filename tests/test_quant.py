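import numpy as np
import pytest

from petmiv.phantom import Lesion, PhantomSpec, generate_phantom
from petmiv.quant import (
    QuantError,
    compute_metrics,
    extract_voi,
    make_parametric,
    quantify_scan,
    reference_mean,
    suv_scale,
)
from petmiv.volumes import InjectionRecord, MaskVolume, ScalarVolume

from oracles import oracle_quantify

SPACING = (2.0, 2.0, 2.0)


def cube_mask(shape, sel=None):
    data = np.ones(shape, dtype=np.uint8) if sel is None else sel.astype(np.uint8)
    return MaskVolume(data, SPACING)


def test_reference_mean_constant_and_two_point():
    pet = ScalarVolume(np.full((4, 4, 4), 5.0), SPACING)
    assert reference_mean(pet, cube_mask((4, 4, 4))) == 5.0
    data = np.zeros((4, 4, 4))
    data[0, 0, 0], data[0, 0, 1] = 2.0, 4.0
    sel = np.zeros((4, 4, 4), dtype=bool)
    sel[0, 0, :2] = True
    assert reference_mean(ScalarVolume(data, SPACING), cube_mask((4, 4, 4), sel)) == 3.0


def test_reference_mean_errors():
    pet = ScalarVolume(np.full((4, 4, 4), 5.0), SPACING)
    empty = cube_mask((4, 4, 4), np.zeros((4, 4, 4), dtype=bool))
    with pytest.raises(QuantError, match="empty"):
        reference_mean(pet, empty)
    zero = ScalarVolume(np.zeros((4, 4, 4)), SPACING)
    with pytest.raises(QuantError, match="> 0"):
        reference_mean(zero, cube_mask((4, 4, 4)))


def test_parametric_self_normalization_and_lesion_ratio():
    data = np.full((6, 6, 6), 40.0)
    data[3, 3, 3] = 120.0
    pet = ScalarVolume(data, SPACING)
    ref_sel = np.zeros((6, 6, 6), dtype=bool)
    ref_sel[0] = True
    par = make_parametric(pet, cube_mask((6, 6, 6), ref_sel))
    assert par.reference_mean == 40.0
    assert par.data[0, 0, 0] == 1.0
    assert par.data[3, 3, 3] == 3.0
    assert abs(par.data[ref_sel].mean() - 1.0) < 1e-9


def test_parametric_scale_invariance():
    rng = np.random.default_rng(0)
    data = rng.uniform(10, 50, (6, 6, 6))
    ref_sel = np.zeros((6, 6, 6), dtype=bool)
    ref_sel[:2] = True
    ref = cube_mask((6, 6, 6), ref_sel)
    base = make_parametric(ScalarVolume(data, SPACING), ref)
    doubled = make_parametric(ScalarVolume(2.0 * data, SPACING), ref)
    np.testing.assert_allclose(doubled.data, base.data, rtol=1e-12)


def test_voi_boundary_value_included():
    """A voxel at exactly the threshold ratio belongs to the VOI (>= rule)."""
    data = np.full((5, 5, 5), 10.0)
    data[2, 2, 2] = 20.0  # exactly 2x the reference mean
    pet = ScalarVolume(data, SPACING)
    ref_sel = np.zeros((5, 5, 5), dtype=bool)
    ref_sel[0] = True
    par = make_parametric(pet, cube_mask((5, 5, 5), ref_sel))
    voi = extract_voi(par, cube_mask((5, 5, 5)))
    assert voi.data[2, 2, 2] == 1
    assert voi.voxel_count == 1


def test_uniform_parametric_gives_empty_voi_with_flag():
    pet = ScalarVolume(np.full((5, 5, 5), 7.0), SPACING)
    lung = cube_mask((5, 5, 5))
    par = make_parametric(pet, lung)
    voi = extract_voi(par, lung)
    assert voi.voxel_count == 0
    m = compute_metrics(pet, par, voi, lung)
    assert m.empty_voi
    assert m.miv_cm3 == m.miv_pct == m.tlg == m.suv_max == m.suv_mean == 0.0


def test_empty_lung_mask_errors():
    pet = ScalarVolume(np.full((5, 5, 5), 7.0), SPACING)
    par = make_parametric(pet, cube_mask((5, 5, 5)))
    empty = cube_mask((5, 5, 5), np.zeros((5, 5, 5), dtype=bool))
    with pytest.raises(QuantError, match="lung mask is empty"):
        extract_voi(par, empty)


def test_planted_sphere_matches_brute_force_oracle(sphere_phantom):
    ph = sphere_phantom
    metrics, voi, par = quantify_scan(ph.pet, ph.lung, ph.reference)
    oracle = oracle_quantify(
        ph.pet.data, ph.lung.data, ph.reference.data, ph.pet.spacing, 2.0
    )
    assert voi.voxel_count == len(oracle["voi"])
    assert sorted(map(tuple, np.argwhere(voi.data))) == oracle["voi"]
    assert metrics.miv_cm3 == pytest.approx(oracle["miv_cm3"], rel=1e-12)
    assert metrics.suv_mean == pytest.approx(oracle["suv_mean"], rel=1e-12)
    # uniform lesion: SUVmax = SUVmean = 3x background, TLG = 3bg * MIV
    assert metrics.suv_max == metrics.suv_mean == pytest.approx(300.0)
    assert metrics.tlg == pytest.approx(3 * 100.0 * metrics.miv_cm3)


def test_miv_volume_arithmetic():
    """1000 VOI voxels at 2 mm isotropic spacing give exactly 8 cm^3."""
    shape = (20, 10, 10)
    data = np.full(shape, 1.0)
    sel = np.zeros(shape, dtype=bool)
    sel[:10] = True  # 1000 voxels
    data[sel] = 3.0
    pet = ScalarVolume(data, SPACING)
    lung = cube_mask(shape)
    ref_sel = np.zeros(shape, dtype=bool)
    ref_sel[15:] = True
    par = make_parametric(pet, cube_mask(shape, ref_sel))
    voi = extract_voi(par, lung)
    m = compute_metrics(pet, par, voi, lung)
    assert m.voi_voxel_count == 1000
    assert m.miv_cm3 == pytest.approx(8.0)
    assert m.miv_pct == pytest.approx(100.0 * 1000 / 2000)
    assert m.tlg == pytest.approx(m.miv_cm3 * m.suv_mean, rel=1e-12)


def test_voi_requires_subset_of_lung():
    shape = (5, 5, 5)
    pet = ScalarVolume(np.ones(shape), SPACING)
    par = make_parametric(pet, cube_mask(shape))
    lung_sel = np.zeros(shape, dtype=bool)
    lung_sel[0] = True
    voi_sel = np.zeros(shape, dtype=bool)
    voi_sel[1] = True
    with pytest.raises(QuantError, match="subset"):
        compute_metrics(pet, par, cube_mask(shape, voi_sel), cube_mask(shape, lung_sel))


def test_exclusion_mask_removes_hotspot():
    spec = PhantomSpec(cardiac_hotspot=True)
    ph = generate_phantom(spec)
    # deliberately sloppy lung segmentation that swallows the hot spot
    sloppy = MaskVolume(
        (ph.lung.as_bool() | ph.exclusions.as_bool()).astype(np.uint8),
        ph.lung.spacing,
    )
    par = make_parametric(ph.pet, ph.reference)
    voi_plain = extract_voi(par, sloppy)
    voi_excl = extract_voi(par, sloppy, exclusions=ph.exclusions)
    assert voi_plain.voxel_count == ph.exclusions.voxel_count > 0
    assert voi_excl.voxel_count == 0


def test_min_component_filter_removes_specks():
    shape = (12, 12, 12)
    data = np.full(shape, 1.0)
    data[2:5, 2:5, 2:5] = 3.0  # 27-voxel blob
    data[9, 9, 9] = 3.0        # single-voxel speck
    pet = ScalarVolume(data, SPACING)
    lung = cube_mask(shape)
    ref_sel = np.zeros(shape, dtype=bool)
    ref_sel[:, :, 11] = True
    par = make_parametric(pet, cube_mask(shape, ref_sel))
    assert extract_voi(par, lung).voxel_count == 28
    assert extract_voi(par, lung, min_component_voxels=2).voxel_count == 27


def test_threshold_monotonicity(sphere_phantom):
    ph = sphere_phantom
    par = make_parametric(ph.pet, ph.reference)
    counts = [
        extract_voi(par, ph.lung, threshold_factor=t).voxel_count
        for t in (1.5, 2.0, 2.5, 3.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_suv_scale_identities():
    shape = (4, 4, 4)
    inj = InjectionRecord(150.0, 50.0, 0.0)
    # whole-body mean activity = dose/weight (kBq/g) -> SUV 1
    act = inj.injected_activity_mbq * 1000.0 / (inj.body_weight_kg * 1000.0)
    vol = ScalarVolume(np.full(shape, act), SPACING)
    suv = suv_scale(vol, inj)
    np.testing.assert_allclose(suv.data, 1.0, rtol=1e-12)
    # halving the dose doubles every SUV
    half = InjectionRecord(75.0, 50.0, 0.0)
    np.testing.assert_allclose(suv_scale(vol, half).data, 2.0, rtol=1e-12)
    # one half-life of uptake time doubles SUV vs zero interval
    delayed = InjectionRecord(150.0, 50.0, 109.77, half_life_min=109.77)
    np.testing.assert_allclose(suv_scale(vol, delayed).data, 2.0, rtol=1e-12)


def test_quantify_scan_suv_flag():
    ph = generate_phantom(PhantomSpec())
    m_raw, _, _ = quantify_scan(ph.pet, ph.lung, ph.reference)
    assert not m_raw.suv_scaled
    m_suv, _, _ = quantify_scan(
        ph.pet, ph.lung, ph.reference,
        injection=InjectionRecord(150.0, 50.0, 60.0),
    )
    assert m_suv.suv_scaled
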