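import numpy as np
import pytest

from vestibulum import AirwaySpec, CenterlineAirway, generate, presets


@pytest.fixture(scope="session")
def preset_specs():
    return presets()


@pytest.fixture(scope="session")
def pano_st(preset_specs):
    return generate(preset_specs["panoplosaurus-st"])


@pytest.fixture(scope="session")
def euo_st(preset_specs):
    return generate(preset_specs["euoplocephalus-st"])


@pytest.fixture(scope="session")
def euo_bb(preset_specs):
    return generate(preset_specs["euoplocephalus-bb"])


@pytest.fixture(scope="session")
def micro(preset_specs):
    return generate(preset_specs["micro"])


@pytest.fixture
def straight_tube():
    """Factory: noise-free straight duct with uniform circular caliber."""

    def build(length_mm=500.0, caliber_mm=8.0, seed=0, spacing_mm=1.0):
        spec = AirwaySpec(
            vestibule_length=length_mm, vestibule_caliber=caliber_mm,
            n_loops=0, loop_plane_extent=length_mm,
            cnp_length=1.0, cnp_caliber=caliber_mm,
            duct_length=1.0, duct_caliber=caliber_mm,
            trachea_length=1.0, trachea_caliber=caliber_mm,
            caliber_noise_cv=0.0, seed=seed, name="tube",
        )
        return generate(spec, spacing_mm=spacing_mm)

    return build


def build_airway(s, diam_mm, points, regions, name="fixture", variant="custom"):
    """Hand-rolled airway from arc positions (m), calibers (mm), points (m)."""
    d = np.asarray(diam_mm, dtype=float) * 1e-3
    return CenterlineAirway(
        name=name, variant=variant,
        s=np.asarray(s, dtype=float),
        area=np.pi * d**2 / 4.0,
        perimeter=np.pi * d,
        points=np.asarray(points, dtype=float),
        region=np.asarray(regions, dtype=object),
    )
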