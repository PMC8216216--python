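"""Sensor calibration two ways: water column and syringe compression.

A pressure sensor reports volts; the device needs kPa.  Known pressures
are applied — hydrostatic columns (P = rho g h) or Boyle's-law syringe
compression — and a line is fitted to (voltage, pressure) pairs.  The
slope and intercept are what gets programmed into the instrument.
"""

import pneumatron as pn

# --- water column: three heights against a sensor reading 0.2 V per kPa
setup = pn.CalibrationSetup()  # water, rho = 1000 kg/m^3, g = 9.81 m/s^2
heights = [0.25, 0.50, 1.00]
pressures_kpa = [pn.water_column_pressure(setup, h) / 1000.0 for h in heights]
voltages = [0.1 + 0.2 * p for p in pressures_kpa]  # synthetic sensor response
fit = pn.fit_calibration(voltages, pressures_kpa)
print("water column:")
for h, p in zip(heights, pressures_kpa):
    print(f"  h = {h:4.2f} m  ->  {p:6.3f} kPa")
print(f"  fit: pressure = {fit.slope:.3f} * V + {fit.intercept:.3f}  "
      f"(r^2 = {fit.r_squared:.6f})")

# --- syringe: 60 mL of air compressed isothermally (relative pressure)
print("syringe (60 mL start, 100 kPa ambient):")
for v in (50.0, 40.0, 30.0):
    print(f"  {v:.0f} mL -> {pn.syringe_pressure(60.0, v, 100.0):6.1f} kPa")
# 20, 50 and 100 kPa: the three classic checkpoints of this calibration.
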