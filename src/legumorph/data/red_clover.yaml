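# Red clover (Trifolium pratense cv. Formica) -- crown-former tolerant to defoliation.
# Printed anchors: petiole 290 mm, internode 87.8 mm, leaf area 64.3 cm2 (2014);
# primary axes faster than the main axis; branching delay between A (2) and KC (8).
name: red_clover
code: RC
phy0: 55.0          # degree-days per phytomer (interpolated)
br1: 3.5
phy1: 1.10
phy2: 0.65
ram_dist: 6.0
d95_lf: 3.0
d95_pet: 3.0
d95_in: 3.0
t50_pet: 0.4
t50_in: 0.8
max_pet: 29.0       # cm
max_in: 8.78        # cm
max_lf: 64.3        # cm2
leaflets: {kind: fixed, count: 3}
has_stipule: false
leaflet_width_ratio: 0.6
profiles:
  leaf: {f0: 0.4, r_peak: 9, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 9, decline: 0.0}
  internode: {f0: 0.4, r_peak: 9, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [phy0, br1, phy1, phy2, ram_dist, d95_lf, d95_pet, d95_in, t50_pet, t50_in, beta, profiles]
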