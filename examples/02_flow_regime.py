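"""Flow-regime diagnostics: Reynolds, Womersley, Reversed-Reynolds flow.

Checks whether resting airflow through a coiled nasal passage is laminar and
quasi-steady, and estimates the largest flow rate that keeps every cross
section laminar (the Reversed-Reynolds approach: solve Re = 4Q/(P nu) for Q
at Re = 2000 and take the minimum over stations).
"""

from vestibulum import (
    generate, presets, regime_report, resistance_parallel, resistance_serial,
)

airway = generate(presets()["euoplocephalus-st"])
rep = regime_report(airway, Q=48.0 / 60e3, breathing_frequency_hz=1.2 / 60.0)
print(f"at 48 L/min: max Re = {rep.max_re:.0f}, max Wo = {rep.max_wo:.2f}")
print(f"Reversed-Reynolds laminar limit: {rep.reversed_reynolds_q_l_min:.1f} L/min")
print(rep.stations.groupby("region", sort=False)[["Re", "Wo"]].max().round(2))

# one wide pipe vs a turbinate-like bank of 14 half-caliber parallel channels
serial = resistance_serial(1.8e-5, 0.1, 0.006)
bank = resistance_parallel([resistance_serial(1.8e-5, 0.1, 0.003)] * 14)
print(f"\nresistance ratio, 14 parallel half-caliber channels vs one pipe: "
      f"{bank / serial:.3f}")
# ~1.14: splitting the airway into parallel channels barely raises resistance,
# which is why turbinate-filled noses are energetically viable.
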