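# Sainfoin (Onobrychis viciifolia cv. Canto) -- crown-former intolerant to defoliation.
# Printed anchors: compound leaves with up to 25 leaflets (Table means 15-16.5);
# leaf-size peak reached only around rank 12; petiole 101 mm, internode 68.0 mm,
# leaf area 73.9 cm2 (2014); primary axes slower than the main axis.
name: sainfoin
code: SF
phy0: 40.0          # degree-days per phytomer (interpolated)
br1: 3.0
phy1: 0.85
phy2: 0.6
ram_dist: 4.0
d95_lf: 3.5
d95_pet: 3.5
d95_in: 3.5
t50_pet: 0.5
t50_in: 1.0
max_pet: 10.1       # cm
max_in: 6.80        # cm
max_lf: 73.9        # cm2
leaflets: {kind: rank_linear, base: 5, cap: 25, cap_rank: 12}
has_stipule: false
leaflet_width_ratio: 0.5
profiles:
  leaf: {f0: 0.4, r_peak: 12, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 12, decline: 0.0}
  internode: {f0: 0.4, r_peak: 12, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [phy0, br1, phy1, phy2, ram_dist, d95_lf, d95_pet, d95_in, t50_pet, t50_in, beta, profiles, leaflets]
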