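# Alfalfa (Medicago sativa cv. Timbale) -- crown-former intolerant to defoliation.
# Printed anchors: branching delay ~2 phyllochrons; whole-phytomer expansion ~5
# phyllochrons; petiole 61.5 mm, internode 85.0 mm, leaf area 33.1 cm2 (2014).
# Entries listed under `interpolated` are non-normative placeholders chosen to
# respect the published orderings (phyllochron: BT-A < SF < WC < RC < KC).
name: alfalfa
code: A
phy0: 33.0          # degree-days per phytomer (interpolated: just above BT's 32.6)
br1: 2.0            # main-axis phyllochrons between primary-axis spawns
phy1: 1.0           # primary relative development rate (primary ~= main in A)
phy2: 0.6           # secondary relative development rate (secondaries much slower)
ram_dist: 2.0       # phyllochrons between phytomer appearance and budburst
d95_lf: 4.0         # phyllochrons
d95_pet: 4.0
d95_in: 4.0
t50_pet: 0.5        # phyllochrons after leaflet half-expansion
t50_in: 1.0         # internodes last: whole-phytomer span = 5 phyllochrons
max_pet: 6.15       # cm
max_in: 8.50        # cm
max_lf: 33.1        # cm2
leaflets: {kind: fixed, count: 3}
has_stipule: false
leaflet_width_ratio: 0.6
profiles:
  leaf: {f0: 0.4, r_peak: 7, decline: 0.0}
  petiole: {f0: 0.4, r_peak: 7, decline: 0.0}
  internode: {f0: 0.4, r_peak: 7, decline: 0.0}
beta: {t_min: 0.0, t_max: 40.0, q: 1.5}   # placeholder response parameters
interpolated: [phy0, br1, phy1, phy2, d95_lf, d95_pet, d95_in, t50_pet, t50_in, beta, profiles]
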