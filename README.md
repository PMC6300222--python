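# vestibulum

Nasal airway heat and water exchange at desk scale — built around the
extreme case of ankylosaurian dinosaurs, whose nasal vestibule is a coiled
tube several times longer than the snout that houses it.

Large-bodied animals face a coupled problem at rest: every breath must be
warmed to body temperature and saturated with water before reaching the
lungs, and whatever heat and moisture leave with the expired air are lost.
A long, convoluted nasal passage works as a counter-current-in-time
exchanger — the mucosal wall absorbs heat from expired air and returns it to
the next inspired breath — and simultaneously as a heat sink that cools
blood bound for the brain.  `vestibulum` provides the pieces needed to
quantify that trade at desk scale, without CT data or 3D CFD:

- **geometry** — centerline airway models (stations of arc position `s`,
  cross-sectional area `A`, wetted perimeter `P`, 3D point, region label),
  per-region length/volume/tortuosity, hydraulic diameter `Dh = 4A/P`, and
  the published model-variant transforms: soft-tissue caliber correction
  (compress a bony-bounded cast to a ~10 mm mucosa-lined caliber),
  *basic* (vestibule collapsed to the straight nostril→CNP line) and
  *straightened* (length kept, curvature removed).
- **synthetic_airway** — seedable parametric generators emulating the
  CT-derived study geometries (coiled vestibule → CNP → nasopharyngeal duct
  → tracheal extension), so the whole pipeline is testable from code alone.
- **flow_regime** — Reynolds `Re = 4Q/(P ν)`, Womersley
  `Wo = (Dh/2)√(2πf/ν)`, laminar/transitional/turbulent and steadiness
  classification, the *Reversed-Reynolds* flow estimator
  `Q = Re·P·ν/4` minimised over cross sections at `Re = 2000` (the largest
  flow that keeps the whole passage laminar), and Hagen–Poiseuille
  serial/parallel duct resistance.
- **psychrometrics** — Magnus saturation vapor pressure, mixing-ratio and
  mass-fraction water content, steam-table latent heat, ideal-gas air
  density.
- **energy_budget** — caloric cost of one breath
  (`sensible = m·Cp·ΔT` with `Cp = 0.24 cal/(g·°C)`,
  `latent = Δm_H2O·ΔH_vap`), recovery on expiration, heat- and
  water-savings fractions (Schmidt-Nielsen), allometric tidal volume
  `VT = 20.3·M^1.06` ml, and the comparative extant-taxa arithmetic.
- **surrogate_exchanger** — a quasi-1D reduced-order exchanger
  (`dT/ds = h_eff·P·(T_wall − T)/(ṁ·cp)`, laminar `Nu₀ = 3.66` with a
  Dean-number curvature enhancement, Lewis-analogy mass transfer) that
  stands in for 3D CFD: axial temperature/humidity profiles, exit states,
  per-region heating shares, and a savings-ranked sweep over airway
  variants and flow rates.

## Worked example

```python
from vestibulum import (BreathScenario, expiration_savings, tidal_volume,
                        water_savings_fraction)

vt_l = round(tidal_volume(2000.0) / 1000.0)          # 64 L per breath
scen = BreathScenario(expired_temperature=15.87, tidal_volume_l=vt_l)
b = expiration_savings(scen)
print(b.sensible_cost, b.latent_cost)                # 352, 1271 cal
print(b.sensible_saved, b.heat_savings_fraction)     # 337 cal, 0.849
print(water_savings_fraction(scen))                  # 0.804
```

A 2000 kg animal breathing 64 L at 15 °C / 50 % relative humidity spends
~352 cal warming the breath by 20 °C and ~1271 cal evaporating the water
that saturates it.  If the nasal passage cools expired air to 15.87 °C, it
claws back 337 cal of sensible heat and ~80 % of the evaporated water.
The `examples/` directory walks each capability: synthetic geometry
(`01`), flow regime and duct resistance (`02`), caloric budgets (`03`), the
quasi-1D exchanger and variant sweep (`04`), and the extant-taxa comparison
(`05`); each prints the numbers it computes with a line on what they mean.

A thin CLI mirrors the library for file-based workflows:

```bash
vestibulum synth --preset euoplocephalus-st -o euo.csv
vestibulum geom metrics euo.csv --region vestibule
vestibulum regime euo.csv --reversed-reynolds
vestibulum budget --profile euoplocephalus --expired-temp 15.87
```

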