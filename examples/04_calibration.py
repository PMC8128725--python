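"""Calibrate the synthetic reporting speed to a measured turnaround target.

Bisects on the mean reporting gap until a FIFO simulation reproduces a
target average report turnaround time — here the 80 minutes measured in
the hospital whose workflow the defaults emulate.
"""

import numpy as np

from worklistsim import (
    SimulationConfig,
    calibrate_reporting_mean,
    default_catalog,
    default_histograms,
    default_timing_params,
    run_simulation,
)

target = 80.0
params = calibrate_reporting_mean(target, default_timing_params(), n_days=100)
print(f"calibrated mean reporting gap: {params.reporting_mean_delta:.2f} min")

# verify on an independent seed
arrival, reporting = default_histograms(params)
config = SimulationConfig(
    strategy="fifo", n_days=200, catalog=default_catalog(),
    arrival_hist=arrival, reporting_hist=reporting, master_seed=99,
)
records = run_simulation(config)
mean_rtat = float(np.mean([r.rtat for r in records]))
print(f"independent-seed FIFO grand mean RTAT: {mean_rtat:.1f} min "
      f"(target {target:.0f} min)")
print(
    "\nA ~12-minute reporting gap against a 12-minute daytime arrival gap\n"
    "keeps the day near saturation, which is what stretches a few-minute\n"
    "read into an ~80-minute average turnaround."
)
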