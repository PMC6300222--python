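"""Quasi-1D heat/moisture exchanger: analytic oracles and directional physics."""

import math
import warnings

import numpy as np
import pytest

from vestibulum import (
    AirState,
    ExchangerConfig,
    WallProperties,
    air_density,
    default_profiles,
    make_basic,
    make_straightened,
    simulate_expiration,
    simulate_inspiration,
    variant_sweep,
    water_mass_fraction,
)
from vestibulum.flow import FluidProperties

DRY = ExchangerConfig(include_moisture=False, curvature_enhancement=False)


def exponential_exit_temperature(tube, Q, t0=15.0, tw=35.0):
    """Closed-form constant-coefficient solution for a uniform straight duct."""
    fl = FluidProperties()
    wall = WallProperties()
    P = float(tube.perimeter[0])
    dh = 4.0 * float(tube.area[0]) / P
    h = 3.66 * fl.thermal_conductivity / dh
    h_eff = 1.0 / (1.0 / h + wall.thickness / wall.conductivity)
    m_dot = Q * air_density(t0)
    L = float(tube.s[-1])
    return tw - (tw - t0) * math.exp(-h_eff * P * L / (m_dot * fl.specific_heat))


def test_exit_temperature_matches_closed_form_to_1e6(straight_tube):
    tube = straight_tube(length_mm=500.0, caliber_mm=8.0)
    res = simulate_inspiration(tube, 2e-4, config=DRY)
    expected = exponential_exit_temperature(tube, 2e-4)
    assert abs(res.exit_temperature - expected) / abs(expected) < 1e-6


def test_long_tube_equilibrates_to_wall_state(straight_tube):
    tube = straight_tube(length_mm=3000.0, caliber_mm=4.0)
    res = simulate_inspiration(tube, 5e-5, config=ExchangerConfig())
    assert res.exit_temperature == pytest.approx(35.0, abs=0.01)
    assert res.exit_water == pytest.approx(
        water_mass_fraction(AirState.saturated(35.0)), abs=0.05)


def test_energy_conservation_along_duct(euo_st):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = simulate_inspiration(euo_st, 48.0 / 60e3,
                                   config=ExchangerConfig(include_moisture=False))
    p = res.profile
    flux = np.trapezoid(p["hP_W_mK"] * (p["wall_T_C"] - p["T_air_C"]), p["s_m"])
    gain = res.m_dot * FluidProperties().specific_heat * (res.exit_temperature - 15.0)
    assert abs(flux - gain) / gain < 1e-3


def test_exit_temperature_monotone_in_length_and_flow(straight_tube):
    short = simulate_inspiration(straight_tube(length_mm=300.0), 2e-4, config=DRY)
    long_ = simulate_inspiration(straight_tube(length_mm=600.0), 2e-4, config=DRY)
    assert long_.exit_temperature > short.exit_temperature
    slow = simulate_inspiration(straight_tube(length_mm=300.0), 1e-4, config=DRY)
    fast = simulate_inspiration(straight_tube(length_mm=300.0), 4e-4, config=DRY)
    assert slow.exit_temperature > fast.exit_temperature


def test_curvature_is_the_only_difference_between_coiled_and_straightened(euo_st):
    # with the Dean enhancement off, identical (s, A, P) must give identical physics
    flat = make_straightened(euo_st)
    cfg = ExchangerConfig(curvature_enhancement=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = simulate_inspiration(euo_st, 48.0 / 60e3, config=cfg)
        b = simulate_inspiration(flat, 48.0 / 60e3, config=cfg)
    assert a.exit_temperature == pytest.approx(b.exit_temperature, abs=1e-9)
    np.testing.assert_allclose(a.profile["T_air_C"], b.profile["T_air_C"], atol=1e-9)


def test_curvature_enhancement_improves_heat_transfer(euo_st):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        on = simulate_inspiration(euo_st, 48.0 / 60e3, config=ExchangerConfig())
        off = simulate_inspiration(euo_st, 48.0 / 60e3,
                                   config=ExchangerConfig(curvature_enhancement=False))
    assert on.exit_temperature > off.exit_temperature + 1.0


def test_grid_convergence(preset_specs):
    from vestibulum import generate

    coarse = generate(preset_specs["panoplosaurus-st"], spacing_mm=1.0)
    fine = generate(preset_specs["panoplosaurus-st"], spacing_mm=0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = simulate_inspiration(coarse, 37.0 / 60e3)
        b = simulate_inspiration(fine, 37.0 / 60e3)
    assert abs(a.exit_temperature - b.exit_temperature) < 0.1


def test_region_heating_shares_sum_to_one(euo_st):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = simulate_inspiration(euo_st, 48.0 / 60e3)
    assert sum(res.region_heating_share.values()) == pytest.approx(1.0, abs=1e-6)
    # the long coiled vestibule dominates the warming, as in the CFD study
    assert res.region_heating_share["vestibule"] >= 0.9
    assert res.exit_temperature > 25.0  # most of the 15 -> 35 degC span covered


def test_turbulent_range_flow_warns(euo_st):
    with pytest.warns(UserWarning, match="Re"):
        simulate_inspiration(euo_st, 110.0 / 60e3)


# -- expiration --------------------------------------------------------------

def euo_pair(euo_st, Q, config=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        insp = simulate_inspiration(euo_st, Q, config=config)
        exp = simulate_expiration(euo_st, Q, insp, config=config)
    return insp, exp


def test_expiration_with_body_temperature_walls_recovers_nothing(euo_st):
    cfg = ExchangerConfig(wall_mode="uniform_offset", wall_offset_c=0.0)
    insp, exp = euo_pair(euo_st, 48.0 / 60e3, cfg)
    assert exp.exit_temperature == pytest.approx(35.0, abs=1e-9)


def test_expired_air_exits_between_ambient_and_body_temperature(euo_st):
    insp, exp = euo_pair(euo_st, 48.0 / 60e3)
    assert 15.0 <= exp.exit_temperature <= 35.0
    assert exp.exit_temperature < 35.0  # mirror walls really recover heat


def test_expiration_rejects_mismatched_geometry(euo_st, pano_st):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        insp = simulate_inspiration(euo_st, 48.0 / 60e3)
        with pytest.raises(ValueError, match="different geometry"):
            simulate_expiration(pano_st, 48.0 / 60e3, insp)


def test_basic_variant_expires_warmer_than_soft_tissue(pano_st):
    # the truncated vestibule cannot cool expired air as far: published
    # direction is 26.5 degC (basic) vs 19.48 degC (ST) at the nostril
    Q = 37.0 / 60e3
    basic = make_basic(pano_st)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        st_exp = simulate_expiration(pano_st, Q, simulate_inspiration(pano_st, Q))
        basic_exp = simulate_expiration(basic, Q, simulate_inspiration(basic, Q))
    assert basic_exp.exit_temperature > st_exp.exit_temperature + 4.0


# -- variant sweep -----------------------------------------------------------

@pytest.fixture(scope="module")
def euo_sweep(euo_st):
    return variant_sweep(euo_st, default_profiles()["euoplocephalus"])


def test_sweep_ranks_soft_tissue_above_straightened_above_basic(euo_sweep):
    at_low = euo_sweep[euo_sweep["flow"] == "low"].set_index("variant")["total_saved_cal"]
    assert at_low["ST"] > at_low["straightened"] > at_low["basic"]


def test_sweep_lower_flow_always_saves_more(euo_sweep):
    for variant in euo_sweep["variant"].unique():
        sub = euo_sweep[euo_sweep["variant"] == variant].set_index("flow")
        assert sub.loc["low", "total_saved_cal"] > sub.loc["high", "total_saved_cal"]


def test_sweep_is_sorted_with_fractions_in_unit_interval(euo_sweep):
    saved = euo_sweep["total_saved_cal"].to_numpy()
    assert np.all(np.diff(saved) <= 0)
    assert euo_sweep["heat_savings_fraction"].between(0, 1).all()
    assert euo_sweep["water_savings_fraction"].between(0, 1).all()


def test_single_variant_single_flow_sweep(euo_st):
    out = variant_sweep(euo_st, default_profiles()["euoplocephalus"],
                        variants=("ST",), flows=("low",))
    assert len(out) == 1
    assert 0.0 <= out.loc[0, "heat_savings_fraction"] <= 1.0
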