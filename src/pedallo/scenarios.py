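"""Simulation-estimation study driver.

One *scenario* is a design cell: an age group, a pediatric sample size, a
sampling scheme, and optionally a pooled intensively-sampled adult arm.  One
*replicate* runs the whole cycle — rebuild the weight pools with fresh
z-draws, sample the cohort, simulate concentrations, fit the NLME model with
both allometric exponents free — and records the estimated exponents.
Replicates are fully determined by (master_seed, scenario label, replicate
index), so any single replicate can be reproduced in isolation and scenarios
can be executed in any order or in parallel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import (
    AGE_GROUPS,
    AgeGroup,
    LMSRecord,
    generate_adult_population,
    generate_pediatric_pool,
    sample_adult_study,
    sample_cohort,
    synthetic_lms_table,
)
from .nlme import EstimationSpec, FitResult, fit_nlme
from .pk import (
    SCHEMES,
    DosingRegimen,
    PKDataset,
    PopulationPKParams,
    SamplingScheme,
    simulate_dataset,
)

__all__ = [
    "ScenarioSpec",
    "ReplicateResult",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "pediatric_grid",
    "pooled_grid",
    "STUDY_SAMPLE_SIZES",
]

#: sample sizes explored in the study design grid
STUDY_SAMPLE_SIZES = (30, 60, 120, 200, 240)


def _as_group(g) -> AgeGroup:
    return AGE_GROUPS[g] if isinstance(g, str) else g


def _as_scheme(s) -> SamplingScheme:
    return SCHEMES[s] if isinstance(s, str) else s


@dataclass(frozen=True)
class ScenarioSpec:
    """One design cell of the simulation-estimation grid."""

    age_group: str | AgeGroup = "2-17"
    n_pediatric: int = 60
    scheme: str | SamplingScheme = "peak_terminal_5"
    pool_adults: bool = False
    n_adults: int = 20
    adult_scheme: str | SamplingScheme = "adult_intensive"
    n_replicates: int = 100
    master_seed: int = 0
    n_per_age: int = 100
    shared_z: bool = False
    pop: PopulationPKParams = field(default_factory=PopulationPKParams)
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    estimation: EstimationSpec = field(default_factory=EstimationSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_group", _as_group(self.age_group))
        object.__setattr__(self, "scheme", _as_scheme(self.scheme))
        object.__setattr__(self, "adult_scheme", _as_scheme(self.adult_scheme))

    @property
    def ped_label(self) -> str:
        """Pediatric design cell; pooled and pediatric-only variants share it
        (and hence share pediatric draws — the comparisons are matched)."""
        return f"{self.age_group.label}_n{self.n_pediatric}_{self.scheme.name}"

    @property
    def label(self) -> str:
        tag = self.ped_label
        if self.pool_adults:
            tag += f"_plus{self.n_adults}adults_{self.adult_scheme.name}"
        return tag

    def with_(self, **kw) -> "ScenarioSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    exp_v_hat: float
    exp_cl_hat: float
    converged: bool
    objective: float


@dataclass
class ScenarioResult:
    """Per-replicate estimates plus design-cell summary statistics."""

    spec: ScenarioSpec
    replicates: list
    fits: list | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(scenario=self.spec.label, replicate=r.replicate,
                     exp_v_hat=r.exp_v_hat, exp_cl_hat=r.exp_cl_hat,
                     converged=r.converged, objective=r.objective)
                for r in self.replicates
            ]
        )

    @property
    def convergence_rate(self) -> float:
        return float(np.mean([r.converged for r in self.replicates]))

    @property
    def reliable(self) -> bool:
        return self.convergence_rate >= 0.5

    def summary(self) -> dict:
        """Quartiles and bias over converged replicates only."""
        conv = [r for r in self.replicates if r.converged]
        out = dict(
            scenario=self.spec.label,
            age_group=self.spec.age_group.label,
            n_pediatric=self.spec.n_pediatric,
            scheme=self.spec.scheme.name,
            pool_adults=self.spec.pool_adults,
            n_replicates=len(self.replicates),
            n_converged=len(conv),
            convergence_rate=self.convergence_rate,
            reliable=self.reliable,
        )
        for name, truth in (("exp_v", self.spec.pop.exp_v), ("exp_cl", self.spec.pop.exp_cl)):
            vals = np.array([getattr(r, f"{name}_hat") for r in conv])
            if vals.size:
                q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
                out.update({f"{name}_q25": float(q25), f"{name}_median": float(med),
                            f"{name}_q75": float(q75), f"{name}_bias": float(vals.mean() - truth),
                            f"{name}_iqr_width": float(q75 - q25)})
            else:
                out.update({f"{name}_q25": np.nan, f"{name}_median": np.nan,
                            f"{name}_q75": np.nan, f"{name}_bias": np.nan,
                            f"{name}_iqr_width": np.nan})
        return out


def _replicate_seed(spec: ScenarioSpec, replicate_index: int) -> np.random.SeedSequence:
    """Child seed: SeedSequence keyed on (master_seed, crc32(ped_label), index)."""
    scen_key = zlib.crc32(spec.ped_label.encode())
    return np.random.SeedSequence(
        entropy=spec.master_seed, spawn_key=(scen_key, replicate_index)
    )


def build_replicate_dataset(
    spec: ScenarioSpec, replicate_index: int, lms_table: Sequence[LMSRecord] | None = None
) -> PKDataset:
    """Pools -> cohort -> simulated concentrations for one replicate."""
    lms = lms_table if lms_table is not None else synthetic_lms_table()
    ss = _replicate_seed(spec, replicate_index)
    s_pool, s_cohort, s_adpop, s_adsample, s_sim_ped, s_sim_ad = ss.spawn(6)

    pool = generate_pediatric_pool(
        lms, spec.age_group, n_per_age=spec.n_per_age, seed=s_pool, shared_z=spec.shared_z
    )
    cohort = sample_cohort(pool, spec.n_pediatric, seed=s_cohort)
    ds = simulate_dataset(cohort, spec.regimen, spec.scheme, spec.pop, seed=s_sim_ped)

    if spec.pool_adults:
        adult_pool = generate_adult_population(seed=s_adpop)
        adults = sample_adult_study(adult_pool, spec.n_adults, seed=s_adsample)
        ds_ad = simulate_dataset(adults, spec.regimen, spec.adult_scheme, spec.pop,
                                 seed=s_sim_ad)
        ds = ds.concat(ds_ad)
    return ds


def run_replicate(
    spec: ScenarioSpec, replicate_index: int, lms_table: Sequence[LMSRecord] | None = None
) -> tuple[float, float, FitResult]:
    """One full generate-sample-simulate-fit cycle."""
    ds = build_replicate_dataset(spec, replicate_index, lms_table)
    fit = fit_nlme(ds, spec.estimation)
    return fit.exp_v, fit.exp_cl, fit


def run_scenario(
    spec: ScenarioSpec,
    lms_table: Sequence[LMSRecord] | None = None,
    keep_fits: bool = False,
    log=None,
) -> ScenarioResult:
    """Run all replicates of a scenario and attach summary statistics."""
    lms = lms_table if lms_table is not None else synthetic_lms_table()
    reps: list[ReplicateResult] = []
    fits: list[FitResult] = []
    for i in range(spec.n_replicates):
        ev, ecl, fit = run_replicate(spec, i, lms)
        reps.append(ReplicateResult(i, ev, ecl, fit.converged, fit.objective))
        if keep_fits:
            fits.append(fit)
        if log is not None:
            log(f"{spec.label} rep {i}: exp_v={ev:.3f} exp_cl={ecl:.3f} "
                f"converged={fit.converged}")
    return ScenarioResult(spec=spec, replicates=reps, fits=fits or None)


def run_grid(
    specs: Sequence[ScenarioSpec],
    lms_table: Sequence[LMSRecord] | None = None,
    log=None,
) -> pd.DataFrame:
    """Map run_scenario over a grid; one tidy summary row per scenario.

    A failing scenario is recorded (column ``error``) and the grid continues."""
    lms = lms_table if lms_table is not None else synthetic_lms_table()
    rows = []
    for spec in specs:
        try:
            res = run_scenario(spec, lms, log=log)
            row = res.summary()
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - grid must survive one bad cell
            row = dict(scenario=spec.label, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def pediatric_grid(n_replicates: int = 100, master_seed: int = 0) -> list[ScenarioSpec]:
    """The pediatric-only headline grid: 5 sizes x 3 schemes x 4 age groups."""
    return [
        ScenarioSpec(age_group=g, n_pediatric=n, scheme=s,
                     n_replicates=n_replicates, master_seed=master_seed)
        for g in AGE_GROUPS
        for s in ("sparse", "peak_terminal_5", "dense")
        for n in STUDY_SAMPLE_SIZES
    ]


def pooled_grid(n_replicates: int = 100, master_seed: int = 0) -> list[ScenarioSpec]:
    """Adult-pooling comparison: 4 age groups x {pediatric-only, +20 adults},
    sparse pediatric sampling, n=60."""
    return [
        ScenarioSpec(age_group=g, n_pediatric=60, scheme="sparse", pool_adults=pooled,
                     n_replicates=n_replicates, master_seed=master_seed)
        for g in AGE_GROUPS
        for pooled in (False, True)
    ]
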