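# Kura clover (Trifolium ambiguum cv. Sevanskij) -- rhizome-former.
# Printed anchors: main-axis phyllochron 64.2 degree-days (largest of the six);
# branching delay ~8 phyllochrons; primary axes slower than the main axis;
# petiole 208 mm, internode 62.7 mm, leaf area 37.7 cm2 (2015).
name: kura_clover
code: KC
phy0: 64.2          # degree-days per phytomer
br1: 4.0
phy1: 0.8
phy2: 0.55
ram_dist: 8.0
d95_lf: 4.0
d95_pet: 4.0
d95_in: 4.0
t50_pet: 0.5
t50_in: 1.0
max_pet: 20.8       # cm
max_in: 6.27        # cm
max_lf: 37.7        # cm2
leaflets: {kind: fixed, count: 3}
has_stipule: false
leaflet_width_ratio: 0.6
profiles:
  leaf: {f0: 0.4, r_peak: 9, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 9, decline: 0.0}
  internode: {f0: 0.4, r_peak: 9, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [br1, phy1, phy2, d95_lf, d95_pet, d95_in, t50_pet, t50_in, beta, profiles]
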