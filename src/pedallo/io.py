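"""File formats and configuration: LMS growth-chart tables, NONMEM-style PK
datasets, YAML study configs, and run manifests.

Everything is delimited UTF-8 text with '.' decimals; no binary formats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import LMSRecord, PEDIATRIC_MONTH_RANGE
from .pk import DATASET_COLUMNS, PKDataset, PopulationPKParams
from .scenarios import STUDY_SAMPLE_SIZES, ScenarioSpec

__all__ = [
    "read_lms_table",
    "fixture_lms_path",
    "load_fixture_lms",
    "write_dataset",
    "read_dataset",
    "load_config",
    "echo_config",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# LMS tables
# ---------------------------------------------------------------------------

_COL_ALIASES = {"agemos": "age_months", "age_months": "age_months", "age": "age_months",
                "sex": "sex", "l": "L", "m": "M", "s": "S"}


def read_lms_table(path, sex_mode: str = "combined") -> list[LMSRecord]:
    """Read a weight-for-age LMS table (bundled fixture or an official
    CDC-format file with a Sex column coded 1=male, 2=female).

    Fractional ages (e.g. the half-month grid of the official charts) are
    floored to whole months.  ``sex_mode`` is one of ``combined`` (average
    L, M, S across sexes per month), ``male`` or ``female``.  Records are
    restricted to the pediatric range 24-215 months and must cover it without
    gaps.
    """
    if sex_mode not in ("combined", "male", "female"):
        raise ValueError(f"unknown sex_mode {sex_mode!r}")
    df = pd.read_csv(path)
    cols = {}
    for c in df.columns:
        key = c.strip().lower()
        if key in _COL_ALIASES:
            cols[c] = _COL_ALIASES[key]
    df = df.rename(columns=cols)
    required = {"age_months", "L", "M", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LMS table {path} missing columns: {sorted(missing)}")

    if "sex" in df.columns:
        if sex_mode == "male":
            df = df[df["sex"] == 1]
        elif sex_mode == "female":
            df = df[df["sex"] == 2]
    elif sex_mode != "combined":
        raise ValueError("sex_mode requested but the table has no Sex column")

    df = df.copy()
    df["age_months"] = np.floor(pd.to_numeric(df["age_months"])).astype(int)
    lo, hi = PEDIATRIC_MONTH_RANGE
    df = df[(df["age_months"] >= lo) & (df["age_months"] <= hi)]
    agg = df.groupby("age_months", as_index=False)[["L", "M", "S"]].mean()

    have = set(agg["age_months"])
    gaps = [m for m in range(lo, hi + 1) if m not in have]
    if gaps:
        raise ValueError(f"LMS table {path} missing age-months: {gaps[:10]}"
                         + ("..." if len(gaps) > 10 else ""))
    if (agg["M"] <= 0).any() or (agg["S"] <= 0).any():
        raise ValueError(f"LMS table {path} has nonpositive M or S values")
    agg = agg.sort_values("age_months")
    return [LMSRecord(int(r.age_months), float(r.L), float(r.M), float(r.S))
            for r in agg.itertuples()]


def fixture_lms_path() -> Path:
    """Path of the bundled synthetic LMS fixture table."""
    return Path(resources.files("pedallo").joinpath("data/lms_synthetic.csv"))


def load_fixture_lms() -> list[LMSRecord]:
    return read_lms_table(fixture_lms_path())


# ---------------------------------------------------------------------------
# NONMEM-style datasets
# ---------------------------------------------------------------------------

def write_dataset(dataset: PKDataset, path) -> None:
    """Comma-delimited NONMEM-style file; missing AMT/DV cells left empty.

    Floats are written with 17 significant digits so the round trip is
    bit-exact."""
    dataset.df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> PKDataset:
    """Read and validate a NONMEM-style dataset written by write_dataset."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} missing columns: {missing}")
    df = df[DATASET_COLUMNS]
    # all-integral float columns would otherwise be inferred as integers
    for col in ("TIME", "AMT", "DV", "WT", "NOMDAY"):
        df[col] = df[col].astype(np.float64)
    for col in ("ID", "EVID", "MDV"):
        df[col] = df[col].astype(np.int64)
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["EVID"] == 0:
            if pd.isna(row["DV"]):
                raise ValueError(f"{path}:{line}: observation row (EVID=0) with empty DV")
            if not pd.isna(row["AMT"]):
                raise ValueError(f"{path}:{line}: observation row (EVID=0) with AMT set")
            if row["MDV"] != 0:
                raise ValueError(f"{path}:{line}: observation row must have MDV=0")
        elif row["EVID"] == 1:
            if pd.isna(row["AMT"]):
                raise ValueError(f"{path}:{line}: dose row (EVID=1) with empty AMT")
            if row["MDV"] != 1:
                raise ValueError(f"{path}:{line}: dose row must have MDV=1")
        else:
            raise ValueError(f"{path}:{line}: unsupported EVID {row['EVID']}")
    return PKDataset(df)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "age_group", "n_pediatric", "scheme", "pool_adults", "n_adults",
    "adult_scheme", "n_replicates", "n_per_age", "shared_z",
}
_POP_KEYS = {
    "tv_v", "tv_cl", "tv_ka", "cv_v", "cv_cl", "cv_ka", "corr_v_cl",
    "sigma_prop", "exp_v", "exp_cl", "ref_weight", "cv_mapping",
}


def load_config(path) -> list[ScenarioSpec]:
    """Parse a YAML study config into a list of ScenarioSpec.

    Layout: optional ``master_seed``, optional ``defaults`` (scenario and/or
    population-parameter keys), and a ``scenarios`` list.  Unknown keys and
    out-of-menu sample sizes are warned about but allowed.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    master_seed = int(cfg.get("master_seed", 0))
    defaults = dict(cfg.get("defaults", {}))
    entries = cfg.get("scenarios", [])
    if not isinstance(entries, list):
        raise ValueError("config 'scenarios' must be a list")

    top_unknown = set(cfg) - {"master_seed", "defaults", "scenarios"}
    if top_unknown:
        warnings.warn(f"config: ignoring unknown top-level keys {sorted(top_unknown)}")

    specs = []
    for entry in entries:
        merged = {**defaults, **(entry or {})}
        unknown = set(merged) - _SCENARIO_KEYS - _POP_KEYS
        if unknown:
            warnings.warn(f"config scenario: ignoring unknown keys {sorted(unknown)}")
        pop_kw = {k: merged[k] for k in _POP_KEYS if k in merged}
        scen_kw = {k: merged[k] for k in _SCENARIO_KEYS if k in merged}
        if "n_pediatric" in scen_kw and scen_kw["n_pediatric"] not in STUDY_SAMPLE_SIZES:
            warnings.warn(
                f"sample size {scen_kw['n_pediatric']} is outside the study menu "
                f"{STUDY_SAMPLE_SIZES} (allowed, but noted)")
        spec = ScenarioSpec(master_seed=master_seed,
                            pop=PopulationPKParams(**pop_kw), **scen_kw)
        specs.append(spec)
    return specs


def echo_config(specs: list[ScenarioSpec], master_seed: int | None = None) -> dict:
    """Config dictionary that reproduces the given scenario specs."""
    seeds = {s.master_seed for s in specs}
    if master_seed is None:
        if len(seeds) > 1:
            raise ValueError("specs carry different master seeds; pass one explicitly")
        master_seed = seeds.pop() if seeds else 0
    default_pop = PopulationPKParams()
    out = {"master_seed": master_seed, "scenarios": []}
    for s in specs:
        entry = {
            "age_group": s.age_group.label,
            "n_pediatric": s.n_pediatric,
            "scheme": s.scheme.name,
            "pool_adults": s.pool_adults,
            "n_adults": s.n_adults,
            "adult_scheme": s.adult_scheme.name,
            "n_replicates": s.n_replicates,
            "n_per_age": s.n_per_age,
            "shared_z": s.shared_z,
        }
        for k in sorted(_POP_KEYS):
            val = getattr(s.pop, k)
            if val != getattr(default_pop, k):
                entry[k] = val
        out["scenarios"].append(entry)
    return out


@dataclass
class RunManifest:
    """Everything needed to regenerate a run byte-for-byte."""

    master_seed: int
    version: str
    config: dict = field(default_factory=dict)
    convergence_rates: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
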