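"""Single-replicate Monte Carlo engine.

One replicate seeds every annual TAVR and bioprosthetic-SAVR cohort, samples
each patient's durability and survival, keeps the patients whose valve fails
before death (the competing-risk filter), assigns the failure to a calendar
year, removes surgically redone valves from the candidate pool, applies the
year- and failure-type-specific ViV penetration, and aggregates annual
TAVR-in-SAVR and TAVR-in-TAVR counts. ViV procedures are terminal: they are
never re-seeded as new index TAVR (no third interventions).

Random-number architecture: each (replicate, procedure class, seeding year)
cohort owns an independent substream keyed by a ``SeedSequence`` tuple, and
each failure type owns a penetration substream, so enlarging the horizon or
the ensemble never perturbs other streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    FAILURE_SAVR,
    FAILURE_TAVR,
    PenetrationSchedule,
    RedoSurgerySeries,
    SimulationConfig,
)
from .sampling import assign_risk_class, sample_age, sample_durability, sample_survival
from .volumes import PROC_SAVR, PROC_TAVR

_PROC_CODE = {PROC_TAVR: 1, PROC_SAVR: 2}
_PENETRATION_SALT = 7919  # distinct key-space for the thinning substreams


@dataclass(frozen=True)
class CohortEvents:
    """Failure events for one seeding cohort (parallel per-patient arrays).

    ``candidate`` marks patients whose valve failed strictly before death;
    non-candidates are retained for audit but excluded downstream.
    """

    index_year: int
    index_type: str
    failure_year: np.ndarray  # int, one entry per patient
    candidate: np.ndarray  # bool, one entry per patient

    @property
    def n_patients(self) -> int:
        return self.failure_year.size

    def candidate_failure_years(self) -> np.ndarray:
        return self.failure_year[self.candidate]


@dataclass(frozen=True)
class AnnualViVForecast:
    """One replicate's annual ViV counts over the simulation horizon."""

    years: np.ndarray
    tavr_in_savr: np.ndarray
    tavr_in_tavr: np.ndarray
    replicate_seed: int

    def __post_init__(self) -> None:
        if (self.tavr_in_savr < 0).any() or (self.tavr_in_tavr < 0).any():
            raise ValueError("annual ViV counts must be non-negative")

    @property
    def total_viv(self) -> np.ndarray:
        return self.tavr_in_savr + self.tavr_in_tavr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "tavr_in_savr": self.tavr_in_savr,
                "tavr_in_tavr": self.tavr_in_tavr,
                "total_viv": self.total_viv,
            }
        )


def cohort_rng(replicate_seed: int, procedure: str, year: int) -> np.random.Generator:
    """Independent substream for one (replicate, procedure, seeding-year) cohort."""
    return np.random.default_rng(
        np.random.SeedSequence((int(replicate_seed), _PROC_CODE[procedure], int(year)))
    )


def penetration_rng(replicate_seed: int, failure_type: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            (int(replicate_seed), _PENETRATION_SALT, _PROC_CODE[failure_type])
        )
    )


def simulate_cohort(year: int, procedure: str, n: int, config: SimulationConfig,
                    rng: np.random.Generator) -> CohortEvents:
    """Sample one seeding cohort and return its failure events.

    Each of the ``n`` patients receives an age, risk class, durability and
    survival draw; the failure calendar year is ``year + floor(durability)``
    (or half-up rounding when configured).
    """
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    if n == 0:
        empty_i = np.empty(0, dtype=np.int64)
        return CohortEvents(year, procedure, empty_i, np.empty(0, dtype=bool))

    ages = sample_age(rng, config.age_model, size=n)
    is_low = assign_risk_class(rng, year, procedure, config.risk_mix, size=n)
    durability = sample_durability(rng, procedure, ages, config.durability_models, size=n)
    survival = sample_survival(
        rng, is_low, ages, config.survival_models, size=n,
        max_attained_age=config.max_attained_age,
    )
    candidate = durability < survival
    if config.failure_year_rounding == "floor":
        offsets = np.floor(durability)
    else:  # "half_up"
        offsets = np.floor(durability + 0.5)
    failure_year = year + offsets.astype(np.int64)
    return CohortEvents(year, procedure, failure_year, candidate)


def apply_penetration(candidates_by_year: dict[int, int], failure_type: str,
                      schedule: PenetrationSchedule,
                      rng: np.random.Generator) -> dict[int, int]:
    """Bernoulli-thin candidate counts by the year's penetration fraction.

    Each candidate is treated independently with probability
    ``schedule(failure_type, year)``. Implemented as per-candidate uniform
    comparisons so that, under common random numbers, raising any penetration
    value can only increase treated counts (the uniforms drawn per year
    depend only on the candidate counts, not on the schedule).
    """
    treated: dict[int, int] = {}
    for year in sorted(candidates_by_year):
        count = int(candidates_by_year[year])
        if count < 0:
            raise ValueError(f"negative candidate count in year {year}")
        p = schedule.value(failure_type, year)
        u = rng.random(count)
        treated[year] = int((u < p).sum())
    return treated


def subtract_redo(candidates_by_year: dict[int, int], failure_type: str,
                  redo: RedoSurgerySeries) -> dict[int, int]:
    """Remove surgically redone valves from the candidate pool, clamped >= 0.

    SAVR-after-SAVR counts come off SAVR-failure candidates; SAVR-after-TAVR
    (surgical TAVR explant) counts come off TAVR-failure candidates.
    """
    kind = "savr_after_savr" if failure_type == FAILURE_SAVR else "savr_after_tavr"
    return {
        year: max(0, int(count) - redo.count(kind, year))
        for year, count in candidates_by_year.items()
    }


def run_single_replicate(config: SimulationConfig, replicate_seed: int) -> AnnualViVForecast:
    """Run the full pipeline once and return annual ViV counts.

    For every seeding year and both procedure classes: sample the cohort,
    histogram candidate failures by calendar year (discarding failures beyond
    the horizon), subtract redo surgeries, apply penetration, and accumulate
    TAVR-in-TAVR (TAVR-sourced failures) and TAVR-in-SAVR (SAVR-sourced
    failures).
    """
    if replicate_seed < 0:
        raise ValueError("replicate_seed must be non-negative")
    years = np.arange(config.start_year, config.end_year + 1)
    n_years = years.size

    candidate_hist = {FAILURE_TAVR: np.zeros(n_years, dtype=np.int64),
                      FAILURE_SAVR: np.zeros(n_years, dtype=np.int64)}
    volumes = {PROC_TAVR: config.tavr_volumes, PROC_SAVR: config.savr_volumes}

    for proc in (PROC_TAVR, PROC_SAVR):
        for seed_year in range(config.start_year, config.end_year + 1):
            n = volumes[proc].get(seed_year, 0)
            if n == 0:
                continue
            rng = cohort_rng(replicate_seed, proc, seed_year)
            events = simulate_cohort(seed_year, proc, n, config, rng)
            fy = events.candidate_failure_years()
            fy = fy[fy <= config.end_year]  # beyond-horizon failures discarded
            np.add.at(candidate_hist[proc], fy - config.start_year, 1)

    treated: dict[str, dict[int, int]] = {}
    for failure_type in (FAILURE_TAVR, FAILURE_SAVR):
        counts = {int(y): int(c) for y, c in zip(years, candidate_hist[failure_type])}
        rng = penetration_rng(replicate_seed, failure_type)
        if config.redo_before_penetration:
            counts = subtract_redo(counts, failure_type, config.redo_series)
            counts = apply_penetration(counts, failure_type, config.penetration, rng)
        else:  # sensitivity switch: thin first, then remove redo patients
            counts = apply_penetration(counts, failure_type, config.penetration, rng)
            counts = subtract_redo(counts, failure_type, config.redo_series)
        treated[failure_type] = counts

    tavr_in_tavr = np.array([treated[FAILURE_TAVR][int(y)] for y in years], dtype=np.int64)
    tavr_in_savr = np.array([treated[FAILURE_SAVR][int(y)] for y in years], dtype=np.int64)
    return AnnualViVForecast(years, tavr_in_savr, tavr_in_tavr, int(replicate_seed))
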