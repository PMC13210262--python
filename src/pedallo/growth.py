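"""Virtual body-weight populations for pediatric PK simulation.

Pediatric weights are drawn from growth-chart LMS parameters (Box-Cox power
``L``, median ``M``, coefficient of variation ``S``) via the quantile map

    weight(z) = M * (1 + z*L*S)**(1/L),        L != 0
    weight(z) = M * exp(z*S),                   L == 0 (log-normal limit)

one z-score per virtual child, 100 children per age-month by default.  Adults
come from a truncated normal (mean 70 kg, sd 10 kg, bounds 60-110 kg).  Study
cohorts are simple random samples without replacement from these pools.

Children younger than 24 months are outside the scope of every routine here:
immunoglobulin handling changes too quickly below that age for a pure
body-weight model to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LMSRecord",
    "Subject",
    "AgeGroup",
    "AGE_GROUPS",
    "PEDIATRIC_MONTH_RANGE",
    "lms_weight",
    "generate_pediatric_pool",
    "sample_cohort",
    "generate_adult_population",
    "sample_adult_study",
    "synthetic_lms_table",
]

#: inclusive month range covered by the pediatric machinery (2-17 y.o.)
PEDIATRIC_MONTH_RANGE = (24, 215)

_L_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class LMSRecord:
    """One growth-chart row: LMS parameters for a single age in months."""

    age_months: int
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError(f"M must be positive, got {self.M} at {self.age_months} mo")
        if self.S <= 0:
            raise ValueError(f"S must be positive, got {self.S} at {self.age_months} mo")


@dataclass(frozen=True)
class Subject:
    """A virtual individual; adults carry no age (it plays no role in the model)."""

    id: str
    cohort: str  # "pediatric" | "adult"
    age_months: int | None
    weight_kg: float

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.cohort not in ("pediatric", "adult"):
            raise ValueError(f"unknown cohort {self.cohort!r}")


@dataclass(frozen=True)
class AgeGroup:
    """An age band, inclusive in integer months."""

    label: str
    lo_months: int
    hi_months: int

    def months(self) -> range:
        return range(self.lo_months, self.hi_months + 1)

    def __len__(self) -> int:
        return self.hi_months - self.lo_months + 1


#: the four study age bands (2-5, 6-11, 12-17 and pooled 2-17 years)
AGE_GROUPS: dict[str, AgeGroup] = {
    "2-5": AgeGroup("2-5", 24, 71),
    "6-11": AgeGroup("6-11", 72, 143),
    "12-17": AgeGroup("12-17", 144, 215),
    "2-17": AgeGroup("2-17", 24, 215),
}


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def lms_weight(z, rec: LMSRecord):
    """Map standard-normal score(s) ``z`` to weight (kg) under an LMS record.

    Raises ``ValueError`` when ``1 + z*L*S <= 0`` (the requested quantile lies
    outside the chart's valid range).  Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    if abs(rec.L) < _L_ZERO_TOL:
        out = rec.M * np.exp(z * rec.S)
    else:
        arg = 1.0 + z * rec.L * rec.S
        if np.any(arg <= 0.0):
            raise ValueError(
                f"z outside valid LMS domain at {rec.age_months} mo "
                f"(1 + z*L*S must be positive)"
            )
        out = rec.M * arg ** (1.0 / rec.L)
    return float(out) if out.ndim == 0 else out


def _valid_z(z: np.ndarray, rec: LMSRecord) -> np.ndarray:
    if abs(rec.L) < _L_ZERO_TOL:
        return np.ones_like(z, dtype=bool)
    return 1.0 + z * rec.L * rec.S > 0.0


def _lms_index(lms_table: Sequence[LMSRecord]) -> dict[int, LMSRecord]:
    return {rec.age_months: rec for rec in lms_table}


def generate_pediatric_pool(
    lms_table: Sequence[LMSRecord],
    group: AgeGroup,
    n_per_age: int = 100,
    seed=None,
    shared_z: bool = False,
) -> list[Subject]:
    """Build the virtual weight pool for one age group.

    Each age-month contributes ``n_per_age`` subjects with fresh standard
    normal z draws mapped through that month's LMS record; z values outside
    the record's valid domain are redrawn.  Month-level randomness is keyed on
    the month itself, so the 2-17 pool is the exact union of the three
    sub-group pools built from the same seed.

    ``shared_z=True`` reuses one set of ``n_per_age`` z draws for every month
    (an alternative reading of "a standard normal distribution ... with 100
    datapoints"); the default draws independently per month.
    """
    idx = _lms_index(lms_table)
    missing = [m for m in group.months() if m not in idx]
    if missing:
        raise ValueError(f"LMS table missing age-months: {missing[:5]}" +
                         ("..." if len(missing) > 5 else ""))

    base = _seed_sequence(seed)
    shared = None
    if shared_z:
        shared = np.random.default_rng(
            np.random.SeedSequence(entropy=base.entropy, spawn_key=base.spawn_key + (0,))
        ).standard_normal(n_per_age)

    subjects: list[Subject] = []
    for month in group.months():
        rec = idx[month]
        if shared_z:
            z = shared.copy()
            # shared draws may still violate a month's domain; redraw locally
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=base.entropy, spawn_key=base.spawn_key + (month,))
            )
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=base.entropy, spawn_key=base.spawn_key + (month,))
            )
            z = rng.standard_normal(n_per_age)
        bad = ~_valid_z(z, rec)
        while np.any(bad):
            z[bad] = rng.standard_normal(int(bad.sum()))
            bad = ~_valid_z(z, rec)
        w = lms_weight(z, rec)
        subjects.extend(
            Subject(id=f"ped_m{month}_{k}", cohort="pediatric", age_months=month,
                    weight_kg=float(w[k]))
            for k in range(n_per_age)
        )
    return subjects


def sample_cohort(pool: Sequence[Subject], n: int, seed=None) -> list[Subject]:
    """Simple random sample of ``n`` subjects without replacement."""
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from pool of {len(pool)}")
    rng = np.random.default_rng(_seed_sequence(seed))
    take = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in take]


def generate_adult_population(
    n: int = 200,
    mean_kg: float = 70.0,
    sd_kg: float = 10.0,
    lo: float = 60.0,
    hi: float = 110.0,
    seed=None,
) -> list[Subject]:
    """Virtual adult pool: normal(mean, sd) truncated to [lo, hi] by rejection."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    rng = np.random.default_rng(_seed_sequence(seed))
    weights = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean_kg, sd_kg, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        weights[filled : filled + draw.size] = draw
        filled += draw.size
    return [
        Subject(id=f"adult_{k}", cohort="adult", age_months=None, weight_kg=float(weights[k]))
        for k in range(n)
    ]


def sample_adult_study(pop: Sequence[Subject], n: int = 20, seed=None) -> list[Subject]:
    """Sample the adult study arm (Phase-1-sized, default 20) from the adult pool."""
    return sample_cohort(pop, n, seed=seed)


# ---------------------------------------------------------------------------
# Synthetic growth chart
# ---------------------------------------------------------------------------

# Sex-combined anchor values patterned on public weight-for-age reference
# charts (median M in kg; S the generalized CV; L the Box-Cox skewness power).
_ANCHOR_MONTHS = np.array([24, 36, 48, 60, 72, 84, 96, 108, 120, 132, 144, 156, 168, 180, 192, 204, 215])
_ANCHOR_M = np.array([12.4, 14.0, 16.1, 18.2, 20.5, 23.0, 25.9, 29.1, 32.5, 36.5, 41.0, 45.8, 50.5, 54.5, 57.7, 60.1, 61.7])
_ANCHOR_S = np.array([0.105, 0.108, 0.115, 0.125, 0.135, 0.155, 0.175, 0.195, 0.210, 0.217, 0.220, 0.215, 0.210, 0.200, 0.195, 0.190, 0.185])
_ANCHOR_L = np.array([-0.15, -0.20, -0.30, -0.38, -0.45, -0.50, -0.55, -0.58, -0.60, -0.60, -0.60, -0.58, -0.55, -0.52, -0.50, -0.47, -0.45])


def synthetic_lms_table() -> list[LMSRecord]:
    """Synthetic month-by-month LMS table for ages 24-215 months.

    A smooth, monotone-in-age stand-in for an official weight-for-age chart
    (synthetic: it is generated from anchor values, not measured data).  The
    median rises from ~12 kg at age 2 to ~62 kg at age 18; skewness (L < 0)
    and relative spread (S) peak around early adolescence, giving the heavy
    right tail characteristic of real weight distributions.
    """
    from scipy.interpolate import PchipInterpolator

    months = np.arange(PEDIATRIC_MONTH_RANGE[0], PEDIATRIC_MONTH_RANGE[1] + 1)
    m = PchipInterpolator(_ANCHOR_MONTHS, _ANCHOR_M)(months)
    s = PchipInterpolator(_ANCHOR_MONTHS, _ANCHOR_S)(months)
    l = PchipInterpolator(_ANCHOR_MONTHS, _ANCHOR_L)(months)
    return [
        LMSRecord(age_months=int(mo), L=float(li), M=float(mi), S=float(si))
        for mo, li, mi, si in zip(months, l, m, s)
    ]
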