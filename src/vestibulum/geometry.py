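"""Centerline airway geometry.

An airway is represented as an ordered sequence of stations along the duct
centerline.  Each station carries its arc-length position ``s`` (m), the
cross-sectional area (m^2), the wetted perimeter (m), the 3D centerline
coordinate (m), and an anatomical region label.  This 1D abstraction is all
that the downstream flow-regime, energy-budget and exchanger calculations
consume: hydraulic diameter, curvature, and per-region lengths and volumes
all derive from it, so no surface mesh is required.

Anatomical regions, nostril to throat:

``vestibule``
    The rostral, tube-like (in ankylosaurs: long and coiled) portion of the
    nasal passage; the principal heat-exchange surface.
``cnp``
    Cavum nasi proprium, the expanded main nasal chamber.
``olfactory_recess``
    Blind side chamber off the CNP; not on the main respiratory path.
``nasopharyngeal_duct``
    Passage from the CNP to the choana.
``tracheal_extension``
    Artificial downstream extension standing in for larynx/trachea.

All quantities are SI internally; reporting helpers convert to the
mm / mm^3 / L·min conventions used in the comparative literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGIONS",
    "MAIN_PATH_REGIONS",
    "Station",
    "CenterlineAirway",
    "InvalidGeometryError",
    "hydraulic_diameter",
    "mean_caliber",
    "region_metrics",
    "menger_curvature",
    "make_basic",
    "make_straightened",
    "soft_tissue_correct",
]

#: Anatomical ordering of region labels along the main flow path.
MAIN_PATH_REGIONS = ("vestibule", "cnp", "nasopharyngeal_duct", "tracheal_extension")

#: All recognised region labels (the olfactory recess is a blind side chamber).
REGIONS = ("vestibule", "cnp", "olfactory_recess", "nasopharyngeal_duct", "tracheal_extension")

_VARIANTS = ("BB", "ST", "basic", "straightened", "custom")


class InvalidGeometryError(ValueError):
    """Raised when a station or airway violates a geometric invariant."""


@dataclass(frozen=True)
class Station:
    """A single cross-section along the airway centerline."""

    s: float
    area: float
    perimeter: float
    point: tuple[float, float, float]
    region: str

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise InvalidGeometryError(
                f"station at s={self.s}: area and perimeter must be positive"
            )
        # Isoperimetric bound: no closed curve encloses its area with less
        # perimeter than a circle (small slack for round-off).
        if self.perimeter < 2.0 * math.sqrt(math.pi * self.area) * (1.0 - 1e-9):
            raise InvalidGeometryError(
                f"station at s={self.s}: perimeter {self.perimeter} below the "
                f"isoperimetric minimum for area {self.area}"
            )
        if self.region not in REGIONS:
            raise InvalidGeometryError(f"unknown region label {self.region!r}")


@dataclass
class CenterlineAirway:
    """Ordered stations defining a duct from nostril to throat.

    Stations are stored as parallel numpy arrays for vectorised metrics;
    :meth:`stations` yields :class:`Station` views.  ``meta`` carries
    provenance (generator seed, transform reports) and is preserved by IO.
    """

    name: str
    variant: str
    s: np.ndarray                # (n,) arc-length positions, m
    area: np.ndarray             # (n,) cross-sectional areas, m^2
    perimeter: np.ndarray        # (n,) wetted perimeters, m
    points: np.ndarray           # (n, 3) centerline coordinates, m
    region: np.ndarray           # (n,) region labels
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.perimeter = np.asarray(self.perimeter, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.region = np.asarray(self.region, dtype=object)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = self.s.size
        if n < 2:
            raise InvalidGeometryError("an airway needs at least 2 stations")
        if not (self.area.size == self.perimeter.size == self.points.shape[0] == self.region.size == n):
            raise InvalidGeometryError("station arrays must have equal length")
        if self.variant not in _VARIANTS:
            raise InvalidGeometryError(f"unknown variant {self.variant!r}")
        if abs(self.s[0]) > 1e-12:
            raise InvalidGeometryError("arc length must start at 0")
        ds = np.diff(self.s)
        if np.any(ds <= 0):
            i = int(np.argmax(ds <= 0))
            raise InvalidGeometryError(f"arc length not strictly increasing at row {i + 1}")
        bad = np.where(~np.isin(self.region, REGIONS))[0]
        if bad.size:
            raise InvalidGeometryError(f"unknown region label at row {bad[0]}")
        if np.any(self.area <= 0) or np.any(self.perimeter <= 0):
            i = int(np.argmax((self.area <= 0) | (self.perimeter <= 0)))
            raise InvalidGeometryError(f"non-positive area/perimeter at row {i}")
        iso = 2.0 * np.sqrt(np.pi * self.area)
        if np.any(self.perimeter < iso * (1.0 - 1e-9)):
            i = int(np.argmax(self.perimeter < iso * (1.0 - 1e-9)))
            raise InvalidGeometryError(f"perimeter below isoperimetric minimum at row {i}")
        # arc length bounds chord length (allow round-off slack)
        chords = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        viol = chords > ds * (1.0 + 1e-9) + 1e-12
        if np.any(viol):
            i = int(np.argmax(viol))
            raise InvalidGeometryError(
                f"chord exceeds arc-length increment between rows {i} and {i + 1}"
            )
        # anatomical ordering of main-path regions (by first appearance)
        first = {r: int(np.argmax(self.region == r)) for r in MAIN_PATH_REGIONS
                 if np.any(self.region == r)}
        order = [first[r] for r in MAIN_PATH_REGIONS if r in first]
        if order != sorted(order):
            raise InvalidGeometryError("main-path regions out of anatomical order")

    # -- convenience --------------------------------------------------------

    def __len__(self) -> int:
        return int(self.s.size)

    def stations(self):
        """Yield :class:`Station` views in order."""
        for i in range(len(self)):
            yield Station(
                s=float(self.s[i]),
                area=float(self.area[i]),
                perimeter=float(self.perimeter[i]),
                point=tuple(self.points[i]),
                region=str(self.region[i]),
            )

    def main_path_mask(self, include_trachea: bool = True) -> np.ndarray:
        """Boolean mask of stations on the respiratory flow path.

        The olfactory recess is a blind side chamber and is always excluded;
        the artificial tracheal extension is excluded on request.
        """
        mask = self.region != "olfactory_recess"
        if not include_trachea:
            mask &= self.region != "tracheal_extension"
        return mask

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise InvalidGeometryError(f"unknown region label {region!r}")
        return self.region == region

    def copy(self) -> "CenterlineAirway":
        return CenterlineAirway(
            name=self.name,
            variant=self.variant,
            s=self.s.copy(),
            area=self.area.copy(),
            perimeter=self.perimeter.copy(),
            points=self.points.copy(),
            region=self.region.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# per-station / per-region metrics
# ---------------------------------------------------------------------------

def hydraulic_diameter(station_or_area, perimeter=None):
    """Hydraulic diameter Dh = 4 A / P (m).

    Accepts a :class:`Station`, or ``(area, perimeter)`` scalars/arrays.
    For a circular section Dh equals the geometric diameter; any
    non-circular section of equal area has a larger perimeter and hence a
    smaller Dh.
    """
    if isinstance(station_or_area, Station):
        a, p = station_or_area.area, station_or_area.perimeter
    else:
        a, p = station_or_area, perimeter
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(a <= 0) or np.any(p <= 0):
        raise InvalidGeometryError("area and perimeter must be positive")
    out = 4.0 * a / p
    return float(out) if out.ndim == 0 else out


def mean_caliber(airway: CenterlineAirway, region: str | None = None) -> float:
    """Arc-length-weighted mean hydraulic diameter, in mm.

    With ``region=None`` the average runs over the whole airway; otherwise
    over the stations carrying that label.
    """
    if region is None:
        idx = np.arange(len(airway))
    else:
        idx = np.where(airway.region_mask(region))[0]
        if idx.size == 0:
            raise InvalidGeometryError(f"region {region!r} absent from airway {airway.name!r}")
    dh = hydraulic_diameter(airway.area[idx], airway.perimeter[idx])
    s = airway.s[idx]
    if idx.size == 1:
        return float(dh) * 1e3
    return float(np.trapezoid(dh, s) / (s[-1] - s[0])) * 1e3


def region_metrics(airway: CenterlineAirway, region: str) -> dict:
    """Length (mm), volume (mm^3) and tortuosity of one region.

    Length is the arc-length span of the region's stations; volume is the
    trapezoidal integral of area over s; tortuosity is arc length over the
    straight-line distance between the region's endpoints (>= 1).
    """
    idx = np.where(airway.region_mask(region))[0]
    if idx.size == 0:
        raise InvalidGeometryError(f"region {region!r} absent from airway {airway.name!r}")
    s = airway.s[idx]
    length = float(s[-1] - s[0])
    volume = float(np.trapezoid(airway.area[idx], s))
    chord = float(np.linalg.norm(airway.points[idx[-1]] - airway.points[idx[0]]))
    tortuosity = length / chord if chord > 0 else math.inf
    return {
        "length_mm": length * 1e3,
        "volume_mm3": volume * 1e9,
        "tortuosity": tortuosity,
    }


def menger_curvature(points: np.ndarray) -> np.ndarray:
    """Discrete curvature (1/m) via the circumscribed circle of point triples.

    kappa_i = 4 * area(P_{i-1}, P_i, P_{i+1}) / (|a| |b| |c|) for interior
    points; endpoints copy their neighbours.  Collinear triples give exactly
    zero.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    kappa = np.zeros(n)
    if n < 3:
        return kappa
    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.cross(p1 - p0, p2 - p0)
    tri2 = np.linalg.norm(cross, axis=1)  # 2 * triangle area
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * tri2 / denom, 0.0)
    kappa[1:-1] = k
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    return kappa


# ---------------------------------------------------------------------------
# model-variant transforms
# ---------------------------------------------------------------------------

def _circular_section(diameter: float) -> tuple[float, float]:
    r = diameter / 2.0
    return math.pi * r * r, math.pi * diameter


def make_basic(airway: CenterlineAirway, spacing: float = 1e-3) -> CenterlineAirway:
    """Replace the vestibule by the straight nostril-to-CNP segment.

    Emulates a plesiomorphic, non-elaborated vestibule: a straight tube from
    the nostril to the CNP entry, with circular cross-section at the source
    vestibule's mean caliber.  Downstream geometry is untouched (rebased in
    s).  The relative length reduction, ``(L_orig - L_straight) / L_orig``,
    is recorded in ``meta['length_reduction_pct']``.
    """
    vest = np.where(airway.region_mask("vestibule"))[0]
    cnp = np.where(airway.region_mask("cnp"))[0]
    if vest.size == 0 or cnp.size == 0:
        raise InvalidGeometryError("make_basic requires both vestibule and cnp")
    nostril = airway.points[vest[0]]
    cnp_entry = airway.points[vest[-1]]  # vestibule/CNP junction
    d_line = float(np.linalg.norm(cnp_entry - nostril))
    if d_line <= 0:
        raise InvalidGeometryError("degenerate airway: nostril coincides with CNP entry")
    l_orig = float(airway.s[vest[-1]] - airway.s[vest[0]])
    reduction = (l_orig - d_line) / l_orig * 100.0

    caliber_m = mean_caliber(airway, "vestibule") * 1e-3
    area, perim = _circular_section(caliber_m)

    n = max(2, math.ceil(d_line / spacing))
    step = d_line / n
    t = np.arange(n + 1) * step  # [0, d_line], ending at the CNP junction
    direction = (cnp_entry - nostril) / d_line
    new_pts = nostril[None, :] + t[:, None] * direction[None, :]

    down = np.arange(cnp[0], len(airway))
    s_new = np.concatenate([t, d_line + airway.s[down] - airway.s[vest[-1]]])
    pts_new = np.vstack([new_pts, airway.points[down]])
    area_new = np.concatenate([np.full(n + 1, area), airway.area[down]])
    perim_new = np.concatenate([np.full(n + 1, perim), airway.perimeter[down]])
    region_new = np.concatenate([np.full(n + 1, "vestibule", dtype=object), airway.region[down]])

    out = CenterlineAirway(
        name=airway.name,
        variant="basic",
        s=s_new,
        area=area_new,
        perimeter=perim_new,
        points=pts_new,
        region=region_new,
        meta={**airway.meta,
              "length_reduction_pct": reduction,
              "source_variant": airway.variant},
    )
    return out


def make_straightened(airway: CenterlineAirway) -> CenterlineAirway:
    """Remove vestibule curvature while conserving its length exactly.

    Every vestibule station keeps its s, area and perimeter; the centerline
    is re-laid along the straight direction from the original vestibule start
    towards the CNP.  Downstream regions translate rigidly to remain attached.
    """
    vest = np.where(airway.region_mask("vestibule"))[0]
    if vest.size == 0:
        raise InvalidGeometryError("make_straightened requires a vestibule")
    start = airway.points[vest[0]]
    end = airway.points[vest[-1]]
    chord = end - start
    norm = float(np.linalg.norm(chord))
    direction = chord / norm if norm > 0 else np.array([1.0, 0.0, 0.0])

    pts = airway.points.copy()
    s_local = airway.s[vest] - airway.s[vest[0]]
    pts[vest] = start[None, :] + s_local[:, None] * direction[None, :]
    shift = pts[vest[-1]] - end
    after = np.arange(vest[-1] + 1, len(airway))
    pts[after] = airway.points[after] + shift[None, :]

    return CenterlineAirway(
        name=airway.name,
        variant="straightened",
        s=airway.s.copy(),
        area=airway.area.copy(),
        perimeter=airway.perimeter.copy(),
        points=pts,
        region=airway.region.copy(),
        meta={**airway.meta, "source_variant": airway.variant},
    )


def soft_tissue_correct(airway: CenterlineAirway, target_caliber_mm: float = 10.0) -> CenterlineAirway:
    """Compress a bony-bounded airway to a mucosa-lined caliber.

    Fossil airway casts are bounded by bone; in life mucosa, cartilage and
    vasculature narrow the lumen, and surveyed amniote airways do not exceed
    ~10 mm mean caliber regardless of body size.  A single shape-preserving
    scale factor k = target / current mean vestibule caliber is applied to
    every station (area by k^2, perimeter by k); the centerline is unchanged.
    """
    if target_caliber_mm <= 0:
        raise InvalidGeometryError("target caliber must be positive")
    if airway.variant != "BB":
        raise InvalidGeometryError("soft-tissue correction expects a bony-bounded (BB) airway")
    current = mean_caliber(airway, "vestibule")
    k = target_caliber_mm / current
    return CenterlineAirway(
        name=airway.name,
        variant="ST",
        s=airway.s.copy(),
        area=airway.area * k * k,
        perimeter=airway.perimeter * k,
        points=airway.points.copy(),
        region=airway.region.copy(),
        meta={**airway.meta, "st_scale_factor": k, "source_variant": airway.variant},
    )
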