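"""Simulate potential shoot development of white clover and print snapshots.

Potential development is deterministic: phytomers appear once per phyllochron,
every axillary bud on the main and primary axes bursts a fixed number of
phyllochrons after its phytomer, and organs expand along logistics.  The
snapshot columns show how axis counts, total leaf area (cm^2) and main-axis
height (cm) accumulate with thermal time (degree-days).
"""

import numpy as np

import legumorph as lm

config = lm.get_species("white_clover")
horizon = 16 * config.phy0  # 16 main-axis phyllochrons
arch = lm.simulate_development(config, horizon_tt=horizon)

print(f"{config.name}: phy0 = {config.phy0} degree-days, "
      f"branching delay = {config.ram_dist} phyllochrons")
snaps = arch.snapshots(np.linspace(0, horizon, 9))
print(snaps.round(2).to_string(index=False))
print("\nEach row is one thermal-time snapshot; counts and sizes only ever "
      "increase because potential growth has no senescence.")
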