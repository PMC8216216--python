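"""Pre-flight diagnostics: size the discharge tube, then test for leaks.

The discharge tube must match the sample: too small and the pressure
hits the 90 kPa pump-restart threshold mid-measurement; too large and
the pressure signal drowns in sensor error.  The empirical rule is
tube volume (mL) = maximum gas discharge (uL) / 510.2.  Before any
experiment, a blocked-tube run checks the system is tight.
"""

import pneumatron as pn

# --- sizing from a fully dehydrated reference sample
gd_max = 1327.0  # uL, maximum discharge measured on a dry sample
print(f"max discharge {gd_max:.0f} uL -> "
      f"recommended tube {pn.size_discharge_tube(gd_max):.2f} mL")

# --- restart check: an undersized tube trips the 90 kPa pump restart
small = pn.DeviceConfig(tube_volume=0.05, sensor_noise_sd=0.0)
trace = pn.simulate_cycle(small, available_gas_volume=440.0)
t_restart = trace.times[trace.pump_events[0]]
print(f"0.05 mL tube on a dry sample: pump restarts at "
      f"{trace.pressures[trace.pump_events[0]]:.0f} kPa after {t_restart:.1f} s "
      f"-> tube too small")

# --- blocked-tube leak tests
device = pn.DeviceConfig(tube_volume=2.6)
for label, decline in (("tight system", 0.0), ("leaky connection", 0.012)):
    traces = pn.simulate_leak_test(device, n_cycles=12,
                                   per_cycle_decline=decline, rng_seed=8)
    cycles = [pn.extract_endpoints(tr) for tr in traces]
    gd, _ = pn.gas_discharge_series(cycles, device.tube_volume)
    verdict = pn.leak_check(gd["ul_atm"].to_numpy())
    print(f"{label:17s}: {verdict.status:10s} "
          f"(drift {verdict.max_drift_pct:.1f}%, "
          f"decreasing regularly: {verdict.monotone_decreasing})")
# A tight system stays within ~2% drift; regular decline beyond 5% means
# the connection leaks and the experiment would be invalid.
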