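"""Independent brute-force enumeration of the forecast rules.

Valid only for fully degenerate scenarios: point-mass age, durability and
survival distributions, risk-class fractions in {0, 1}, and penetration
fractions in {0, 1}. Under those conditions every patient's fate is
deterministic, so the pipeline can be enumerated patient by patient without
touching the engine's code paths.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def brute_force_forecast(config) -> dict[str, dict[int, int]]:
    """Return {"TAVR": {year: count}, "SAVR": {year: count}} treated counts.

    Keys are failure types (the failed index valve's class); "TAVR" counts are
    TAVR-in-TAVR procedures and "SAVR" counts TAVR-in-SAVR.
    """
    age = int(config.age_model.params["age"])  # point-mass family required
    candidates: dict[str, dict[int, int]] = {
        "TAVR": defaultdict(int),
        "SAVR": defaultdict(int),
    }
    for proc, series in (("TAVR", config.tavr_volumes), ("SAVR", config.savr_volumes)):
        for year, n in series.counts.items():
            if n == 0:
                continue
            frac_low = config.risk_mix.fraction_low(proc, year)
            assert frac_low in (0.0, 1.0), "oracle needs a deterministic risk mix"
            risk = "low" if frac_low == 1.0 else "intermediate_high"
            if proc == "TAVR":
                mix = config.durability_models["TAVR"]
            elif age < 70:
                mix = config.durability_models["SAVR_age_lt_70"]
            else:
                mix = config.durability_models["SAVR_age_ge_70"]
            assert len(mix.components) == 1 and mix.components[0].sd_years == 0.0
            durability = mix.components[0].mean_years
            surv_model = config.survival_models[risk]
            assert surv_model.sd_years == 0.0
            survival = min(surv_model.median_years, config.max_attained_age - age)
            if not durability < survival:
                continue  # died (or tied) before the valve failed
            if config.failure_year_rounding == "floor":
                fy = year + math.floor(durability)
            else:
                fy = year + math.floor(durability + 0.5)
            if fy <= config.end_year:
                for _ in range(n):
                    candidates[proc][fy] += 1

    treated: dict[str, dict[int, int]] = {}
    for failure_type, redo_kind in (("TAVR", "savr_after_tavr"), ("SAVR", "savr_after_savr")):
        out: dict[int, int] = {}
        for year in range(config.start_year, config.end_year + 1):
            count = candidates[failure_type].get(year, 0)
            count = max(0, count - config.redo_series.count(redo_kind, year))
            p = config.penetration.value(failure_type, year)
            assert p in (0.0, 1.0), "oracle needs penetration in {0, 1}"
            out[year] = count if p == 1.0 else 0
        treated[failure_type] = out
    return treated


def random_degenerate_config(rng: np.random.Generator):
    """Draw a random fully degenerate scenario for oracle-equivalence tests."""
    from vivforecast import RedoSurgerySeries, degenerate_config

    start, end = 2000, int(rng.integers(2006, 2015))
    n_cohorts = int(rng.integers(1, 5))
    tavr = {int(rng.integers(start, end + 1)): int(rng.integers(0, 60))
            for _ in range(n_cohorts)}
    savr = {int(rng.integers(start, end + 1)): int(rng.integers(0, 60))
            for _ in range(n_cohorts)}
    redo_years = range(start, end + 1)
    redo = RedoSurgerySeries(
        savr_after_savr={y: int(rng.integers(0, 8)) for y in redo_years},
        savr_after_tavr={y: int(rng.integers(0, 8)) for y in redo_years},
    )
    return degenerate_config(
        tavr_cohorts=tavr,
        savr_cohorts=savr,
        start_year=start,
        end_year=end,
        age=int(rng.integers(60, 96)),
        tavr_durability=float(np.round(rng.uniform(0.5, 12.0), 3)),
        savr_durability_lt70=float(np.round(rng.uniform(0.5, 12.0), 3)),
        savr_durability_ge70=float(np.round(rng.uniform(0.5, 12.0), 3)),
        survival_low=float(np.round(rng.uniform(0.5, 40.0), 3)),
        survival_intermediate_high=float(np.round(rng.uniform(0.5, 15.0), 3)),
        fraction_low_tavr=float(rng.integers(0, 2)),
        fraction_low_savr=float(rng.integers(0, 2)),
        penetration_tavr=float(rng.integers(0, 2)),
        penetration_savr=float(rng.integers(0, 2)),
        redo=redo,
        master_seed=int(rng.integers(0, 2**31)),
    )
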