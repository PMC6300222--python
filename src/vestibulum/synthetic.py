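"""Parametric, seedable airway geometries.

CT-derived ankylosaur airway casts are not redistributable, so every pipeline
stage is exercised on generated stand-ins that reproduce the scalar fields
the analysis consumes: arc length, cross-sectional area, wetted perimeter and
centerline curvature, laid out as vestibule -> CNP -> nasopharyngeal duct ->
tracheal extension.  The vestibule is a planar serpentine coil whose
amplitude is solved so its arc length hits the requested value exactly while
its endpoints span the requested nostril-to-CNP straight-line distance
(``loop_plane_extent``) — emulating the rostral and caudal vestibular loops
of the real specimens without any claim about their true 3D shape.

Cross sections are circular with optional lognormal caliber noise.  The
paper-scale presets pin vestibule lengths and calibers to the published
specimen values; the caliber noise level (CV 0.05 by default) is a synthetic
robustness device with no empirical basis and is labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .geometry import CenterlineAirway

__all__ = ["AirwaySpec", "InfeasibleSpecError", "generate", "presets"]


class InfeasibleSpecError(ValueError):
    """Requested coil cannot exist (e.g. arc length below endpoint span)."""


@dataclass(frozen=True)
class AirwaySpec:
    """Parameters of a generated airway.  Lengths and calibers in mm.

    ``loop_plane_extent`` is the axial span of the vestibular coil: the coil
    runs from the nostril to a point exactly this far away, so it is also the
    straight-line nostril->CNP distance that the ``basic`` variant collapses
    the vestibule onto.
    """

    vestibule_length: float = 200.0
    vestibule_caliber: float = 10.0
    n_loops: int = 2
    loop_plane_extent: float = 100.0
    cnp_length: float = 100.0
    cnp_caliber: float = 25.0
    duct_length: float = 80.0
    duct_caliber: float = 10.0
    trachea_length: float = 80.0
    trachea_caliber: float = 12.0
    caliber_noise_cv: float = 0.05
    seed: int = 0
    name: str = "synthetic"
    variant: str = "custom"

    def __post_init__(self) -> None:
        for field_name in ("vestibule_length", "vestibule_caliber", "loop_plane_extent",
                           "cnp_length", "cnp_caliber", "duct_length", "duct_caliber",
                           "trachea_length", "trachea_caliber"):
            if getattr(self, field_name) <= 0:
                raise ValueError(f"{field_name} must be positive")
        if self.n_loops < 0:
            raise ValueError("n_loops must be >= 0")
        if not 0.0 <= self.caliber_noise_cv < 0.5:
            raise ValueError("caliber_noise_cv must lie in [0, 0.5)")


def _serpentine(length_m: float, span_m: float, n_loops: int, n_dense: int):
    """Dense planar serpentine polyline of given arc length and axial span."""
    if n_loops == 0:
        x = np.linspace(0.0, length_m, n_dense)
        return np.column_stack([x, np.zeros(n_dense), np.zeros(n_dense)])
    if length_m < span_m * (1.0 - 1e-12):
        raise InfeasibleSpecError(
            f"arc length {length_m * 1e3:.2f} mm is shorter than the coil span "
            f"{span_m * 1e3:.2f} mm"
        )
    x = np.linspace(0.0, span_m, n_dense)
    phase = np.sin(2.0 * math.pi * n_loops * x / span_m)

    def polyline_length(amplitude: float) -> float:
        pts = np.column_stack([x, amplitude * phase])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    if length_m <= span_m:
        amp = 0.0
    else:
        hi = span_m
        for _ in range(60):
            if polyline_length(hi) >= length_m:
                break
            hi *= 2.0
        else:
            raise InfeasibleSpecError("cannot reach requested arc length with this loop count")
        amp = brentq(lambda a: polyline_length(a) - length_m, 0.0, hi, xtol=1e-14)
    return np.column_stack([x, amp * phase, np.zeros(n_dense)])


def _resample(dense: np.ndarray, length_m: float, spacing_m: float):
    """Stations at even arc positions along a dense polyline."""
    chords = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chords)])
    u *= length_m / u[-1]  # absorb brentq residual (<1e-12 relative)
    n = max(2, math.ceil(length_m / spacing_m))
    sv = np.linspace(0.0, length_m, n + 1)
    pts = np.column_stack([np.interp(sv, u, dense[:, k]) for k in range(3)])
    return sv, pts


def _circle(diam: np.ndarray):
    return math.pi * diam**2 / 4.0, math.pi * diam


def generate(spec: AirwaySpec, spacing_mm: float = 1.0) -> CenterlineAirway:
    """Build a :class:`CenterlineAirway` from a spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    spacing = spacing_mm * 1e-3
    L = spec.vestibule_length * 1e-3
    span = spec.loop_plane_extent * 1e-3

    n_dense = max(4001, 800 * max(spec.n_loops, 1) + 1)
    dense = _serpentine(L, span, spec.n_loops, n_dense)
    s_v, pts_v = _resample(dense, L, spacing)

    s_all = [s_v]
    pts_all = [pts_v]
    regions = [np.full(s_v.size, "vestibule", dtype=object)]
    diam_all = [_noisy(rng, spec.vestibule_caliber * 1e-3, spec.caliber_noise_cv, s_v.size)]

    cursor_s = s_v[-1]
    cursor_p = pts_v[-1]
    axis = np.array([1.0, 0.0, 0.0])
    for region, length_mm, caliber_mm in (
        ("cnp", spec.cnp_length, spec.cnp_caliber),
        ("nasopharyngeal_duct", spec.duct_length, spec.duct_caliber),
        ("tracheal_extension", spec.trachea_length, spec.trachea_caliber),
    ):
        seg = length_mm * 1e-3
        m = max(1, math.ceil(seg / spacing))
        step = seg / m
        local = np.arange(1, m + 1) * step
        s_all.append(cursor_s + local)
        pts_all.append(cursor_p[None, :] + local[:, None] * axis[None, :])
        regions.append(np.full(m, region, dtype=object))
        diam_all.append(_noisy(rng, caliber_mm * 1e-3, spec.caliber_noise_cv, m))
        cursor_s += seg
        cursor_p = pts_all[-1][-1]

    diam = np.concatenate(diam_all)
    area, perimeter = _circle(diam)
    return CenterlineAirway(
        name=spec.name,
        variant=spec.variant,
        s=np.concatenate(s_all),
        area=area,
        perimeter=perimeter,
        points=np.vstack(pts_all),
        region=np.concatenate(regions),
        meta={"seed": spec.seed, "spec": asdict(spec)},
    )


def _noisy(rng: np.random.Generator, nominal: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, nominal)
    sigma = math.sqrt(math.log1p(cv * cv))
    return nominal * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def presets() -> dict[str, AirwaySpec]:
    """Named specs emulating the study geometries.

    Vestibule lengths and calibers follow the published specimen values
    (Panoplosaurus 440 mm / 15.8 mm BB caliber; Euoplocephalus 808.74 mm /
    22.9 mm; soft-tissue variants at 10 mm).  Coil spans equal the published
    straight-line nostril->CNP distances (200 and 162.14 mm) so the basic
    variant reproduces the published 55% / 80% vestibule shortenings.
    Downstream chamber sizes are plausible round numbers, not measurements.
    A Panoplosaurus vestibule length of 400 mm also appears in the source
    literature's summary table; the 440 mm value is used because it is the
    one consistent with the printed straight-line reduction.
    """
    common_pan = dict(vestibule_length=440.0, n_loops=2, loop_plane_extent=200.0,
                      cnp_length=150.0, duct_length=120.0, trachea_length=100.0)
    common_euo = dict(vestibule_length=808.74, n_loops=2, loop_plane_extent=162.14,
                      cnp_length=180.0, duct_length=140.0, trachea_length=120.0)
    return {
        "panoplosaurus-bb": AirwaySpec(
            name="panoplosaurus-bb", variant="BB", vestibule_caliber=15.8,
            cnp_caliber=40.0, duct_caliber=15.0, trachea_caliber=18.0, **common_pan),
        "panoplosaurus-st": AirwaySpec(
            name="panoplosaurus-st", variant="ST", vestibule_caliber=10.0,
            cnp_caliber=25.0, duct_caliber=10.0, trachea_caliber=15.0, **common_pan),
        "euoplocephalus-bb": AirwaySpec(
            name="euoplocephalus-bb", variant="BB", vestibule_caliber=22.9,
            cnp_caliber=50.0, duct_caliber=18.0, trachea_caliber=20.0, **common_euo),
        "euoplocephalus-st": AirwaySpec(
            name="euoplocephalus-st", variant="ST", vestibule_caliber=10.0,
            cnp_caliber=30.0, duct_caliber=12.0, trachea_caliber=15.0, **common_euo),
        "pigeon": AirwaySpec(
            name="pigeon", variant="custom", vestibule_length=30.0,
            vestibule_caliber=2.0, n_loops=1, loop_plane_extent=18.0,
            cnp_length=20.0, cnp_caliber=5.0, duct_length=10.0, duct_caliber=2.5,
            trachea_length=20.0, trachea_caliber=3.0),
        "micro": AirwaySpec(
            name="micro", variant="custom", vestibule_length=6.0,
            vestibule_caliber=2.0, n_loops=0, loop_plane_extent=6.0,
            cnp_length=1.0, cnp_caliber=4.0, duct_length=1.0, duct_caliber=2.0,
            trachea_length=1.0, trachea_caliber=2.0, caliber_noise_cv=0.0),
    }
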