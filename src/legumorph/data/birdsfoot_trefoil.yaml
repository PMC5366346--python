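# Birdsfoot trefoil (Lotus corniculatus cv. Leo) -- crown-former tolerant to defoliation.
# Printed anchors: main-axis phyllochron 32.6 degree-days (smallest of the six);
# whole-phytomer expansion ~5 phyllochrons; stipules present; petiole 10.6 mm,
# internode 24.2 mm, leaf area 8.9 cm2 (2015).
name: birdsfoot_trefoil
code: BT
phy0: 32.6          # degree-days per phytomer
br1: 2.0
phy1: 1.0           # primary ~= main in BT
phy2: 0.6
ram_dist: 2.5
d95_lf: 4.0
d95_pet: 4.0
d95_in: 4.0
d95_stip: 4.0
t50_pet: 0.5
t50_in: 1.0         # leaf elements first, internodes last: span = 5 phyllochrons
t50_stip: 0.25
max_pet: 1.06       # cm
max_in: 2.42        # cm
max_lf: 8.9         # cm2
max_stip: 1.0       # cm (placeholder; stipule maxima not printed)
leaflets: {kind: fixed, count: 3}
has_stipule: true
leaflet_width_ratio: 0.6
profiles:
  leaf: {f0: 0.4, r_peak: 8, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 8, decline: 0.0}
  internode: {f0: 0.4, r_peak: 8, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [br1, phy1, phy2, ram_dist, d95_lf, d95_pet, d95_in, d95_stip, t50_pet, t50_in, t50_stip, max_stip, beta, profiles]
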