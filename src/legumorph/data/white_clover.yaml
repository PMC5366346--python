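# White clover (Trifolium repens cv. Giga) -- stolon-former.
# Printed anchors: whole-phytomer expansion ~2.5 phyllochrons with internodes
# completing first (negative t50_in); primary axes develop faster than the main
# axis; petiole 261 mm, internode 49.0 mm, leaf area 46 cm2 (2014).
name: white_clover
code: WC
phy0: 46.0          # degree-days per phytomer (interpolated: BT-A < SF < WC < RC < KC)
br1: 2.5
phy1: 1.18          # primary axes faster than the main axis
phy2: 0.7
ram_dist: 3.0
d95_lf: 2.0
d95_pet: 2.0
d95_in: 2.0
t50_pet: 0.25
t50_in: -0.25       # internode-first coordination; span = 2.5 phyllochrons
max_pet: 26.1       # cm
max_in: 4.90        # cm
max_lf: 46.0        # cm2
leaflets: {kind: fixed, count: 3}
has_stipule: false
leaflet_width_ratio: 0.6
profiles:
  leaf: {f0: 0.4, r_peak: 7, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 7, decline: 0.0}
  internode: {f0: 0.4, r_peak: 7, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [phy0, br1, phy1, phy2, ram_dist, beta, profiles]
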