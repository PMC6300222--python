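# Methods

## The model in one paragraph

An airway is a 1D centerline: ordered stations carrying arc position *s*
(m), cross-sectional area *A* (m²), wetted perimeter *P* (m), a 3D
coordinate, and an anatomical region label (vestibule, cavum nasi proprium,
olfactory recess, nasopharyngeal duct, tracheal extension).  Everything
downstream — hydraulic diameter, Reynolds and Womersley numbers, the
Reversed-Reynolds flow bound, duct resistance, and the quasi-1D exchanger —
consumes only these scalar fields plus discrete curvature, so the package
deliberately carries no surface meshes, CT volumes, or 3D flow fields.  The
scientific claim testable at this fidelity is directional and budgetary:
how much heat and water a passage of given length, caliber and coiling can
recover per breath, and how that capacity ranks across airway variants and
flow rates.  Point CFD outputs (exact expired-air temperatures, vortex
structure) are treated as published *inputs* where budgets need them, never
as recomputed claims.

## Geometry and variants

- Hydraulic diameter `Dh = 4A/P`.  Mean caliber of a region is the
  arc-length-weighted (trapezoidal) mean of `Dh`, reported in mm; the
  source literature does not state its weighting, and arc-length weighting
  is the natural choice for a quantity defined along a duct.
- Region length is the arc-length span of the region's stations; volume is
  the trapezoid of `A` over `s`; tortuosity is arc length over endpoint
  separation.
- Discrete curvature is Menger curvature (circumscribed circle of
  consecutive point triples), endpoints copying neighbours; collinear
  triples give exactly zero.
- **Soft-tissue correction**: one global shape-preserving scale factor
  `k = target / mean vestibule caliber` applied to every station (`A·k²`,
  `P·k`), centerline untouched, default target 10 mm — the observed upper
  caliber bound in mucosa-lined amniote airways.
- **Basic**: vestibule replaced by a straight tube from the nostril to the
  vestibule→CNP junction, circular at the source vestibule's mean caliber;
  reported length reduction is `(L_orig − L_straight)/L_orig`.
- **Straightened**: vestibule stations keep `s`, `A`, `P` exactly and are
  re-laid along the original start→end direction; downstream regions
  translate rigidly.  Length, volume and caliber are conserved to the bit;
  curvature is the only thing removed.
- Units are SI internally; reporting converts to mm / mm³ / L·min.
- The Panoplosaurus vestibule length appears in the source literature as
  both 400 mm (summary table) and 440 mm (results text).  Presets use
  440 mm, the value consistent with the published 200 mm straight line and
  55 % reduction; the discrepancy is noted here rather than resolved.

## Synthetic airways

The generator emulates what the analysis needs from a CT cast, not the
cast itself.  The vestibule is a planar serpentine `y = A·sin(2πn·x/D)`
whose amplitude is solved (Brent's method on the dense polyline length) so
the arc length matches the request exactly; `D` (`loop_plane_extent`) is
both the coil's axial span and the straight-line nostril→CNP distance the
basic variant collapses onto.  Downstream regions are straight segments.
Stations are resampled at 1 mm spacing (configurable); station `s` values
are exact arc positions, so region lengths are exact and chord never
exceeds arc.  Cross sections are circular with optional lognormal caliber
noise (mean-one; CV default 0.05 — a robustness device with no empirical
basis, since the source reports no caliber statistics).  A single seeded
`numpy` generator makes output byte-reproducible; the seed is recorded in
the file metadata.

Presets pin the published values: vestibule lengths 440 / 808.74 mm, spans
200 / 162.14 mm, bony-bounded calibers 15.8 / 22.9 mm, soft-tissue caliber
10 mm, two loop groups.  Downstream chamber sizes (CNP ~25–50 mm caliber,
duct ~10–18 mm, ~100–180 mm lengths) are plausible round numbers chosen
once, not measurements.  Circular sections at equal caliber have smaller
wetted perimeter than the real, highly non-circular cross sections; this is
why the published low flow rates (37 / 48 L · min⁻¹, Reversed-Reynolds on
the real geometry) ship as profile constants rather than being recomputed
on synthetic geometry.

## Flow regime

`Re = 4Q/(Pν)` with ν = 1.412e-5 m²/s (air at 15 °C); laminar below 2000,
transitional on the closed interval [2000, 4000], turbulent above — the
boundary values belong to the transition zone because the outer labels are
defined by strict inequalities.  `Wo = (Dh/2)√(2πf/ν)`: quasi-steady below
1, unsteady above 10, intermediate between (boundaries inclusive).  The
Reversed-Reynolds estimator takes the minimum of `Q = Re·P·ν/4` over
main-path stations; the olfactory recess (blind side chamber) is always
excluded and the artificial tracheal extension is excluded by default,
since neither is part of the nasal flow path being bounded.

## Psychrometrics

Magnus saturation pressure `e_s = 610.94·exp(17.625T/(T+243.04))` Pa
(the source does not name its formulation; Magnus is standard and within a
few tenths of a percent over the physiological range).  Water content comes
in two conventions — mixing ratio `w = 0.622·e/(p−e)` (per kg dry air) and
mass fraction `w/(1+w)` (per kg moist air).  The published latent totals
sit between the two conventions (they are mutually inconsistent at the few
percent level), so both are implemented; the budget default is mass
fraction, which lands closer to the published totals (~4–5 % high vs ~9 %
for mixing ratio).  Latent heat interpolates a bundled saturated-steam
table (0–100 °C, 5 °C steps, standard kJ/kg values, converted by 4.184);
extrapolation raises.  Air density is ideal-gas dry air,
`p/(287.05·T_K)` — 1.146 g/L at 35 °C, matching the budget constant.

## Energy and water budgets

Sensible: `m·Cp·ΔT`, `Cp = 0.24 cal/(g·°C)`.  Latent: water moved times
`ΔH_vap` at the *destination* temperature — evaporation priced at body
temperature on inspiration, condensation at expired-air temperature on
expiration.  Expired air is assumed saturated regardless of temperature.
Tidal volume `VT = 20.3·M^1.06` ml (avian fit; the crocodylian coefficient
20.7 raises it ~2 %), air mass `VT·1.146` g.

Rounding: budgets are full precision.  The published tables round
inconsistently — the cost table only reproduces with air mass rounded to
whole grams (73 g × 0.24 × 20 = 350), while the savings tables require full
precision (73.344 g × 0.24 × 15.58 = 274) — so a `printed_mass` switch and
3-significant-figure reporting reproduce the printed rows without
contaminating full-precision work.  The extant-taxa cascade rounds heat
capacity to 3 (inspiratory) / 2 (expiratory) significant figures before
multiplying, which reproduces the printed columns except two rows printed
at yet another precision (noted in tests, covered by a 2 % band).

The headline 84 % efficiency is printed-table arithmetic (recomputed
sensible parts plus published latent totals over the published cost); the
fully recomputed route gives ~85 %, the difference tracing entirely to the
latent-convention ambiguity above.

## Surrogate exchanger

Bulk (mixing-cup) air marches along the centerline:

    dT/ds = h_eff·P·(T_wall − T)/(ṁ·cp)
    dw/ds = h_m·P·(w_sat(T_wall) − w)/ṁ

with `h = Nu·k_air/Dh`, laminar constant-wall-temperature `Nu₀ = 3.66`,
curvature enhancement `Nu = Nu₀(1 + α·√De)`, Dean number
`De = Re·√(Dh·κ/2)` from Menger curvature κ, α = 0.1 (config-exposed);
wall conduction `t/k` (0.5 mm, 0.34 W/m·K) in series with the film; mass
transfer by Lewis analogy (`Sh = Nu`, `h_m = h/cp`).  Temperature and
humidity integrate independently — latent release does not heat the air —
which keeps the sensible balance exact and the two budgets separable, at
the cost of underestimating air temperature where condensation is strong.
Integration is classical RK4, one step per station interval (1 mm default)
with linear interpolation of coefficients; against the closed-form
exponential solution on a uniform duct the exit temperature is accurate to
~1e-14 relative, and halving the spacing moves exit temperatures by far
less than 0.1 °C.

Inspiration holds the wall at body temperature, saturated.  Expiration
enters at the choana end at body temperature, saturated, and — in the
default `mirror` mode — takes the wall temperature profile from the
inspired-air temperature profile: the warming the wall delivered is exactly
the cooling capacity it regained, the recuperator assumption.  A
`uniform_offset` wall (body temperature minus a fixed drop) is the
alternative.  Per-region heating shares are sensible-enthalpy shares by
default (identical to temperature-rise shares at constant cp); a `total`
basis adds latent enthalpy.

**What the surrogate does and does not show.**  It reproduces, from
geometry alone: the published variant ranking (soft-tissue > straightened >
basic at fixed flow), the flow-rate direction (lower flow saves more), the
dominance of the vestibule in heating (≥ 90 % share on the coiled presets),
and energy conservation to numerical precision.  It does *not* reproduce
the CFD's absolute exit temperatures on synthetic geometry: circular
sections at equal caliber under-supply wetted perimeter, and α = 0.1 is a
generic Dean-enhancement level, not a calibration — the
Euoplocephalus-at-48-L/min inspired-air exit lands ~4 °C short of full
body-temperature equilibration rather than within 1 °C.  Passing tests
therefore certify the surrogate's internal physics and directional
agreement, not quantitative CFD equivalence on real anatomy.

## Problem sizes and runtimes

Study-scale geometries resolve to ~800–1250 stations at 1 mm spacing; an
exchanger run takes well under a second, the full test suite a few seconds,
and the acceptance script a few seconds — sizes chosen because grid
convergence is already far below 0.1 °C at 1 mm.

## Known limitations

- 1D bulk model: no secondary-flow fields, no turbulence closure (flows
  beyond Re 4000 only warn), no conjugate wall heat conduction along *s*.
- Circular synthetic cross sections; real airway perimeters are larger at
  equal caliber, so perimeter-driven quantities (Reversed-Reynolds flow,
  film area) are conservative on synthetic geometry.
- Psychrometric convention ambiguity bounds latent totals at the few
  percent level (documented above).
- The olfactory recess is excluded from flow but also from exchange; its
  possible buffering role is out of scope, as are brain-cooling vasculature
  and whole-body thermal balance.
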