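"""Fit the population model to one simulated study and inspect recovery.

The allometric exponents of V/F and CL/F are estimated freely (truth: 1.0
and 0.75).  With n=60 children across ages 2-17, one replicate typically
recovers them to within ~0.1."""

from pedallo import (
    AGE_GROUPS,
    SCHEMES,
    DosingRegimen,
    PopulationPKParams,
    fit_nlme,
    generate_pediatric_pool,
    sample_cohort,
    simulate_dataset,
    synthetic_lms_table,
)

truth = PopulationPKParams()
lms = synthetic_lms_table()
pool = generate_pediatric_pool(lms, AGE_GROUPS["2-17"], seed=20)
cohort = sample_cohort(pool, 60, seed=21)
ds = simulate_dataset(cohort, DosingRegimen(), SCHEMES["peak_terminal_5"], truth, seed=22)

fit = fit_nlme(ds)
print(f"converged: {fit.converged}   -2LL: {fit.objective:.2f} "
      f"({fit.n_function_evals} objective evaluations)")
true_vals = {"tv_v": 18.0, "tv_cl": 1.0, "tv_ka": 0.9, "exp_v": 1.0, "exp_cl": 0.75,
             "corr_v_cl": 0.7, "sigma_prop": 0.25}
for k, v in fit.estimates.items():
    t = true_vals.get(k)
    print(f"  {k:11s} = {v:7.4f}" + (f"   (truth {t})" if t is not None else ""))
print("\nsd_* are the standard deviations of the log-scale random effects;")
print("sd ~ 0.44 corresponds to the simulated ~46% coefficient of variation.")
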