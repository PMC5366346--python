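"""Thermal time from a diurnal temperature trace.

A sinusoidal greenhouse day around 20 deg C accumulates slightly less than the
15 degree-days a constant 20 deg C would give, because the beta response is
concave around its optimum.
"""

import legumorph as lm
from legumorph.synthetic import generate_temperature_series

params = lm.BetaThermalParams(t_min=0.0, t_max=40.0, q=1.5)

constant = generate_temperature_series(mean=20.0, diurnal_amplitude=0.0, days=10.0)
diurnal = generate_temperature_series(mean=20.0, diurnal_amplitude=8.0, days=10.0)

tt_const = lm.thermal_time(constant, params)
tt_diurnal = lm.thermal_time(diurnal, params)
print(f"constant 20 deg C, 10 days : {tt_const:8.2f} degree-days (15 per day)")
print(f"20 +/- 8 deg C sinusoid    : {tt_diurnal:8.2f} degree-days")
print(f"phyllochronic time on a 46 degree-day axis: "
      f"{lm.phyllochronic_time(tt_const, 46.0):.3f} phyllochrons")
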