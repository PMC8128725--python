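"""Compare worklist strategies on common random numbers.

Runs the FIFO baseline, AI priority at the low-FPR operating point, the
same with a 6-hour maximum-waiting-time cap, and the perfect-classifier
upper bound, all on identical arrival/label/service randomness, then
prints mean and max report turnaround time (RTAT) per class.
"""

import pandas as pd

from worklistsim import (
    SimulationConfig,
    compare_strategies,
    default_catalog,
    default_histograms,
    low_fpr_preset,
    run_simulation,
    summarize_rtat,
)

catalog = default_catalog()
arrival, reporting = default_histograms()
common = dict(
    n_days=200, catalog=catalog, arrival_hist=arrival,
    reporting_hist=reporting, master_seed=3,
)

runs = {
    "fifo": run_simulation(SimulationConfig(strategy="fifo", **common)),
    "prio": run_simulation(
        SimulationConfig(strategy="prio", operating_point=low_fpr_preset(), **common)
    ),
    "prio_maxwait": run_simulation(
        SimulationConfig(
            strategy="prio_maxwait", operating_point=low_fpr_preset(),
            t_max=360.0, **common,
        )
    ),
    "perfect": run_simulation(SimulationConfig(strategy="perfect", **common)),
}

tables = {k: summarize_rtat(v, catalog).set_index("class") for k, v in runs.items()}
table = pd.DataFrame(
    {
        k: t["mean_min"].round(1).astype(str) + "/" + t["max_min"].astype(int).astype(str)
        for k, t in tables.items()
    }
)
print(f"mean/max RTAT (min) per class, {len(runs['fifo'])} exams per strategy:\n")
print(table)

welch = compare_strategies(runs["prio"], runs["fifo"], catalog)
p = welch.set_index("class").loc["pneumothorax", "p"]
print(
    f"\nPneumothorax mean drops from "
    f"{tables['fifo'].loc['pneumothorax', 'mean_min']:.1f} to "
    f"{tables['prio'].loc['pneumothorax', 'mean_min']:.1f} min under priority "
    f"(Welch p = {p:.2e}), but its worst case grows; the t_max cap pulls the\n"
    "worst case back down at a small cost in mean, and 'perfect' bounds what\n"
    "any classifier could achieve."
)
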