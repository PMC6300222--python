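"""Centerline geometry: metrics, invariants, model-variant transforms."""

import math

import numpy as np
import pytest

from vestibulum import (
    InvalidGeometryError,
    Station,
    hydraulic_diameter,
    make_basic,
    make_straightened,
    mean_caliber,
    menger_curvature,
    region_metrics,
    soft_tissue_correct,
)
from vestibulum.synthetic import AirwaySpec, generate

from conftest import build_airway


@pytest.mark.parametrize(
    "area,perimeter,expected",
    [
        (math.pi * 0.01**2, 2 * math.pi * 0.01, 0.02),  # circle radius 10 mm -> 2r
        (1.0e-4, 0.05, 8.0e-3),
        (0.004**2, 4 * 0.004, 0.004),                   # square duct side a -> a
    ],
)
def test_hydraulic_diameter_closed_forms(area, perimeter, expected):
    assert hydraulic_diameter(area, perimeter) == pytest.approx(expected, rel=1e-12)


def test_hydraulic_diameter_rejects_nonpositive():
    with pytest.raises(InvalidGeometryError):
        hydraulic_diameter(0.0, 0.05)
    with pytest.raises(InvalidGeometryError):
        hydraulic_diameter(1e-4, -1.0)


def test_station_rejects_subisoperimetric_section():
    # a "cross-section" with less perimeter than the equal-area circle is impossible
    with pytest.raises(InvalidGeometryError):
        Station(s=0.0, area=1e-4, perimeter=0.01, point=(0, 0, 0), region="vestibule")


def test_noncircular_section_has_smaller_dh_than_circle_of_same_perimeter():
    # square of side a: P = 4a; circle of same perimeter has D = 4a/pi > Dh = a
    a = 0.005
    assert hydraulic_diameter(a * a, 4 * a) < 4 * a / math.pi


def test_mean_caliber_uniform_tube(straight_tube):
    tube = straight_tube(length_mm=100.0, caliber_mm=10.0)
    assert mean_caliber(tube, "vestibule") == pytest.approx(10.0, abs=1e-9)


def test_mean_caliber_weights_by_arc_length():
    n = 201
    s = np.linspace(0.0, 1.0, n)
    diam = np.where(s <= 0.5, 8.0, 12.0)
    pts = np.column_stack([s, np.zeros(n), np.zeros(n)])
    aw = build_airway(s, diam, pts, ["vestibule"] * n)
    assert mean_caliber(aw, "vestibule") * 1e-3 == pytest.approx(10.0e-3, abs=2e-5)


def test_mean_caliber_missing_region_errors(micro):
    with pytest.raises(InvalidGeometryError):
        mean_caliber(micro, "olfactory_recess")


def test_region_metrics_straight_tube(straight_tube):
    tube = straight_tube(length_mm=200.0, caliber_mm=10.0)
    m = region_metrics(tube, "vestibule")
    assert m["length_mm"] == pytest.approx(200.0, rel=1e-9)
    assert m["tortuosity"] == pytest.approx(1.0, rel=1e-9)
    # uniform circular tube: V = A L
    assert m["volume_mm3"] == pytest.approx(math.pi * 25.0 * 200.0, rel=1e-9)


def test_region_metrics_helix_matches_analytic_length():
    # helix radius r, pitch p: L = n_turns * sqrt((2 pi r)^2 + p^2)
    r, pitch, turns = 0.02, 0.01, 3
    theta = np.linspace(0.0, 2 * math.pi * turns, 2000)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                           pitch * theta / (2 * math.pi)])
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(chords)])
    aw = build_airway(s, np.full(s.size, 5.0), pts, ["vestibule"] * s.size)
    analytic = turns * math.sqrt((2 * math.pi * r) ** 2 + pitch**2)
    assert region_metrics(aw, "vestibule")["length_mm"] == pytest.approx(
        analytic * 1e3, rel=5e-3)


def test_airway_invariant_violations_are_reported():
    pts = [[0, 0, 0], [0.001, 0, 0], [0.002, 0, 0]]
    with pytest.raises(InvalidGeometryError, match="strictly increasing"):
        build_airway([0.0, 0.002, 0.001], [5, 5, 5], pts, ["vestibule"] * 3)
    with pytest.raises(InvalidGeometryError, match="chord exceeds"):
        build_airway([0.0, 0.0005, 0.001], [5, 5, 5], pts, ["vestibule"] * 3)
    with pytest.raises(InvalidGeometryError, match="anatomical order"):
        build_airway([0.0, 0.001, 0.002], [5, 5, 5], pts,
                     ["cnp", "cnp", "vestibule"])


# -- model-variant transforms ------------------------------------------------

def test_make_basic_reduction_panoplosaurus(pano_st):
    basic = make_basic(pano_st)
    assert basic.variant == "basic"
    # 440 mm coiled vestibule vs 200 mm straight nostril->CNP line
    assert basic.meta["length_reduction_pct"] == pytest.approx(54.5, abs=0.1)
    assert region_metrics(basic, "vestibule")["length_mm"] == pytest.approx(200.0, abs=0.5)
    assert region_metrics(basic, "vestibule")["tortuosity"] == pytest.approx(1.0, abs=1e-9)


def test_make_basic_reduction_euoplocephalus(euo_st):
    basic = make_basic(euo_st)
    assert basic.meta["length_reduction_pct"] == pytest.approx(80.0, abs=0.1)
    assert region_metrics(basic, "vestibule")["length_mm"] == pytest.approx(162.14, abs=0.5)


def test_make_basic_idempotent_on_straight_vestibule(straight_tube):
    tube = straight_tube(length_mm=100.0, caliber_mm=10.0)
    basic = make_basic(tube)
    assert basic.meta["length_reduction_pct"] == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(basic.s, tube.s, atol=1e-12)
    np.testing.assert_allclose(basic.area, tube.area, rtol=1e-12)
    np.testing.assert_allclose(basic.points, tube.points, atol=1e-12)


def test_make_basic_never_lengthens_and_downstream_untouched(euo_st):
    basic = make_basic(euo_st)
    lv_new = region_metrics(basic, "vestibule")["length_mm"]
    lv_old = region_metrics(euo_st, "vestibule")["length_mm"]
    assert lv_new <= lv_old
    for region in ("cnp", "nasopharyngeal_duct", "tracheal_extension"):
        old = region_metrics(euo_st, region)
        new = region_metrics(basic, region)
        assert new["length_mm"] == pytest.approx(old["length_mm"], rel=1e-9)
        assert new["volume_mm3"] == pytest.approx(old["volume_mm3"], rel=1e-9)


def test_make_straightened_conserves_length_volume_and_calibers(euo_st):
    flat = make_straightened(euo_st)
    assert flat.variant == "straightened"
    for region in ("vestibule", "cnp", "nasopharyngeal_duct"):
        old, new = region_metrics(euo_st, region), region_metrics(flat, region)
        assert new["length_mm"] == old["length_mm"]
        assert new["volume_mm3"] == old["volume_mm3"]
    np.testing.assert_array_equal(flat.area, euo_st.area)
    np.testing.assert_array_equal(flat.perimeter, euo_st.perimeter)
    assert region_metrics(flat, "vestibule")["tortuosity"] == pytest.approx(1.0, abs=1e-9)


def test_make_straightened_removes_curvature(euo_st):
    flat = make_straightened(euo_st)
    vest = flat.region == "vestibule"
    before = np.trapezoid(menger_curvature(euo_st.points[vest]), euo_st.s[vest])
    after = np.trapezoid(menger_curvature(flat.points[vest]), flat.s[vest])
    assert before > 1.0  # the coiled source really is curved
    assert after == pytest.approx(0.0, abs=1e-9)


def test_soft_tissue_correct_hits_target_and_scales_volume(euo_bb):
    st = soft_tissue_correct(euo_bb, 10.0)
    assert st.variant == "ST"
    assert mean_caliber(st, "vestibule") == pytest.approx(10.0, abs=0.05)
    k = st.meta["st_scale_factor"]
    v_old = region_metrics(euo_bb, "vestibule")["volume_mm3"]
    v_new = region_metrics(st, "vestibule")["volume_mm3"]
    assert v_new == pytest.approx(v_old * k * k, rel=1e-12)
    np.testing.assert_array_equal(st.points, euo_bb.points)


def test_soft_tissue_correct_identity_and_monotonicity(euo_bb):
    current = mean_caliber(euo_bb, "vestibule")
    same = soft_tissue_correct(euo_bb, current)
    assert same.meta["st_scale_factor"] == pytest.approx(1.0, rel=1e-12)
    small = soft_tissue_correct(euo_bb, 8.0)
    large = soft_tissue_correct(euo_bb, 12.0)
    assert (region_metrics(large, "vestibule")["volume_mm3"]
            > region_metrics(small, "vestibule")["volume_mm3"])


def test_soft_tissue_correct_input_validation(euo_bb, euo_st):
    with pytest.raises(InvalidGeometryError):
        soft_tissue_correct(euo_bb, -1.0)
    with pytest.raises(InvalidGeometryError):
        soft_tissue_correct(euo_st, 10.0)  # already soft-tissue corrected
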