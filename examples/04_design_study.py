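"""Sweep a small study-design grid and summarize exponent recovery.

Each design cell repeats the whole cycle (rebuild pools, sample the cohort,
simulate, fit with both exponents free) and reports the interquartile range
of the estimated exponents across replicates — the study's precision marker.
Ten replicates per cell keep this demo quick; the full design uses 100."""

import pandas as pd

from pedallo import ScenarioSpec, run_grid, synthetic_lms_table

specs = [
    ScenarioSpec(age_group="2-5", n_pediatric=30, scheme="sparse", n_replicates=10),
    ScenarioSpec(age_group="2-17", n_pediatric=30, scheme="sparse", n_replicates=10),
    ScenarioSpec(age_group="2-17", n_pediatric=60, scheme="sparse", n_replicates=10),
    ScenarioSpec(age_group="2-5", n_pediatric=60, scheme="sparse", pool_adults=True,
                 n_replicates=10),
]
table = run_grid(specs, lms_table=synthetic_lms_table())
cols = ["scenario", "convergence_rate", "exp_v_q25", "exp_v_q75",
        "exp_cl_q25", "exp_cl_q75", "exp_cl_iqr_width"]
pd.set_option("display.width", 120)
print(table[cols].round(3).to_string(index=False))
print("\ntruth: exp_v=1.0, exp_cl=0.75.  Narrow IQRs mean the design identifies")
print("the allometric exponents well; note the gain from a broader age range,")
print("larger n, and pooled intensively-sampled adults for young children.")
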