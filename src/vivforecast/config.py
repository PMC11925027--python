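"""Model parameters: types, validation, (de)serialisation, default fixture.

Every tunable of the simulation lives in a :class:`SimulationConfig` that can
be round-tripped through YAML (JSON-compatible schema: no non-string mapping
keys in the serialised form). ``default_config()`` returns the packaged US
scenario encoding the published model parameters; ``load_config`` merges a
partial user file over those defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .volumes import PROC_SAVR, PROC_TAVR, AnnualVolumeSeries, build_savr_series, build_tavr_series

RISK_LOW = "low"
RISK_INTERMEDIATE_HIGH = "intermediate_high"
RISK_CLASSES = (RISK_LOW, RISK_INTERMEDIATE_HIGH)

#: Durability-model stratum keys.
STRATUM_TAVR = "TAVR"
STRATUM_SAVR_LT70 = "SAVR_age_lt_70"
STRATUM_SAVR_GE70 = "SAVR_age_ge_70"

#: Failure-type tags (the type of the failed index valve).
FAILURE_TAVR = "TAVR"
FAILURE_SAVR = "SAVR"

AGE_MIN = 60
AGE_MAX = 95


class ConfigError(ValueError):
    """A configuration file could not be parsed or contains unknown keys."""


class InvariantError(ValueError):
    """A configured value violates a model invariant."""


# ---------------------------------------------------------------------------
# age distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeDistribution:
    """Probability distribution of patient age at the index procedure.

    Support is the integer ages 60..95. Families:

    - ``discretized_normal``: weights proportional to a normal density with
      ``params = {mean, sd}``, renormalised on the support.
    - ``categorical``: explicit ``params = {weights: [36 floats]}``.
    - ``point_mass``: all mass at ``params = {age}``.
    """

    family: str
    params: dict

    @classmethod
    def discretized_normal(cls, mean: float, sd: float) -> "AgeDistribution":
        return cls("discretized_normal", {"mean": float(mean), "sd": float(sd)})

    @classmethod
    def point_mass(cls, age: int) -> "AgeDistribution":
        return cls("point_mass", {"age": int(age)})

    @classmethod
    def categorical(cls, weights) -> "AgeDistribution":
        return cls("categorical", {"weights": [float(w) for w in weights]})

    @property
    def support(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MAX + 1)

    @cached_property
    def weights(self) -> np.ndarray:
        ages = self.support
        if self.family == "discretized_normal":
            mean, sd = float(self.params["mean"]), float(self.params["sd"])
            if sd <= 0:
                raise InvariantError("age distribution sd must be > 0")
            w = np.exp(-0.5 * ((ages - mean) / sd) ** 2)
        elif self.family == "categorical":
            w = np.asarray(self.params["weights"], dtype=float)
            if w.shape != ages.shape:
                raise InvariantError(
                    f"age weights must have length {ages.size} (ages 60..95)"
                )
        elif self.family == "point_mass":
            age = int(self.params["age"])
            if not AGE_MIN <= age <= AGE_MAX:
                raise InvariantError("point-mass age must lie in [60, 95]")
            w = (ages == age).astype(float)
        else:
            raise InvariantError(f"unknown age-distribution family {self.family!r}")
        if (w < 0).any():
            raise InvariantError("age weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise InvariantError("age weights must have positive mass")
        w = w / total
        return w

    def validate(self) -> None:
        w = self.weights
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvariantError("age weights must sum to 1")

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgeDistribution":
        return cls(str(d["family"]), dict(d["params"]))


# ---------------------------------------------------------------------------
# risk mix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskMixEntry:
    """Low-risk fraction for one procedure class over [start_year, end_year)."""

    procedure: str
    start_year: int
    end_year: int  # exclusive
    fraction_low_risk: float

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "start_year": self.start_year,
            "end_year": self.end_year,
            "fraction_low_risk": self.fraction_low_risk,
        }


@dataclass(frozen=True)
class RiskMixSchedule:
    """Era-wise surgical-risk-class mix per procedure class.

    Year ranges are half-open ``[start_year, end_year)`` and must not overlap
    within a procedure class.
    """

    entries: tuple[RiskMixEntry, ...]

    def validate(self) -> None:
        for proc in (PROC_TAVR, PROC_SAVR):
            spans = sorted(
                (e.start_year, e.end_year) for e in self.entries if e.procedure == proc
            )
            for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise InvariantError(
                        f"risk-mix eras overlap for {proc} at year {s1}"
                    )
        for e in self.entries:
            if not 0.0 <= e.fraction_low_risk <= 1.0:
                raise InvariantError(
                    f"fraction_low_risk must be in [0, 1], got {e.fraction_low_risk}"
                )
            if e.start_year >= e.end_year:
                raise InvariantError("risk-mix era must satisfy start_year < end_year")

    def fraction_low(self, procedure: str, year: int) -> float:
        for e in self.entries:
            if e.procedure == procedure and e.start_year <= year < e.end_year:
                return e.fraction_low_risk
        raise InvariantError(f"no risk-mix era covers {procedure} year {year}")

    def covers(self, procedure: str, year: int) -> bool:
        return any(
            e.procedure == procedure and e.start_year <= year < e.end_year
            for e in self.entries
        )

    def to_dict(self) -> dict:
        return {"entries": [e.to_dict() for e in self.entries]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskMixSchedule":
        return cls(
            tuple(
                RiskMixEntry(
                    str(e["procedure"]), int(e["start_year"]), int(e["end_year"]),
                    float(e["fraction_low_risk"]),
                )
                for e in d["entries"]
            )
        )


# ---------------------------------------------------------------------------
# durability and survival distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_years: float
    sd_years: float

    def to_dict(self) -> dict:
        return {"weight": self.weight, "mean_years": self.mean_years, "sd_years": self.sd_years}


@dataclass(frozen=True)
class DurabilityMixture:
    """Mixture-of-normals valve failure-time model, truncated to (0, inf).

    A component with ``sd_years == 0`` is an exact point mass — the degenerate
    limit used by oracle test scenarios.
    """

    components: tuple[MixtureComponent, ...]

    def validate(self) -> None:
        if not self.components:
            raise InvariantError("durability mixture needs at least one component")
        wsum = sum(c.weight for c in self.components)
        if abs(wsum - 1.0) > 1e-9:
            raise InvariantError(f"mixture weights must sum to 1, got {wsum}")
        for c in self.components:
            if not 0.0 < c.weight <= 1.0:
                raise InvariantError("mixture weights must lie in (0, 1]")
            if c.mean_years <= 0:
                raise InvariantError("mixture mean_years must be > 0")
            if c.sd_years < 0:
                raise InvariantError("mixture sd_years must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean_years for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd_years for c in self.components])

    def to_dict(self) -> dict:
        return {"family": "normal_mixture", "components": [c.to_dict() for c in self.components]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DurabilityMixture":
        return cls(
            tuple(
                MixtureComponent(float(c["weight"]), float(c["mean_years"]), float(c["sd_years"]))
                for c in d["components"]
            )
        )

    @classmethod
    def single(cls, mean_years: float, sd_years: float) -> "DurabilityMixture":
        return cls((MixtureComponent(1.0, mean_years, sd_years),))


@dataclass(frozen=True)
class SurvivalDistribution:
    """Post-procedure survival-time model for one surgical-risk class.

    ``truncated_normal`` with mean = median (symmetry), truncated to (0, inf)
    by rejection; ``sd_years == 0`` is an exact point mass.
    """

    family: str
    median_years: float
    sd_years: float

    def validate(self) -> None:
        if self.family != "truncated_normal":
            raise InvariantError(f"unknown survival family {self.family!r}")
        if self.median_years <= 0:
            raise InvariantError("survival median_years must be > 0")
        if self.sd_years < 0:
            raise InvariantError("survival sd_years must be >= 0")

    def to_dict(self) -> dict:
        return {"family": self.family, "median_years": self.median_years, "sd_years": self.sd_years}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurvivalDistribution":
        return cls(str(d["family"]), float(d["median_years"]), float(d["sd_years"]))


# ---------------------------------------------------------------------------
# penetration schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PenetrationSchedule:
    """Per-year fraction of failed valves treated by ViV, per failure type.

    Anchors are (year, fraction) pairs; the schedule is flat before the first
    anchor, linearly interpolated between anchors, and flat after the last —
    the simplest monotone reading of a "progressive increase".
    """

    tavr_failure: tuple[tuple[int, float], ...]
    savr_failure: tuple[tuple[int, float], ...]

    def _anchors(self, failure_type: str) -> tuple[tuple[int, float], ...]:
        if failure_type == FAILURE_TAVR:
            return self.tavr_failure
        if failure_type == FAILURE_SAVR:
            return self.savr_failure
        raise InvariantError(f"unknown failure type {failure_type!r}")

    def validate(self) -> None:
        for ft in (FAILURE_TAVR, FAILURE_SAVR):
            anchors = self._anchors(ft)
            if not anchors:
                raise InvariantError(f"penetration schedule for {ft} failures is empty")
            years = [a[0] for a in anchors]
            if any(y1 <= y0 for y0, y1 in zip(years, years[1:])):
                raise InvariantError("penetration anchor years must be strictly increasing")
            for _, f in anchors:
                if not 0.0 <= f <= 1.0:
                    raise InvariantError(f"penetration fractions must be in [0, 1], got {f}")

    def value(self, failure_type: str, year: int) -> float:
        anchors = self._anchors(failure_type)
        xs = np.array([a[0] for a in anchors], dtype=float)
        fs = np.array([a[1] for a in anchors], dtype=float)
        return float(np.interp(year, xs, fs))

    def with_anchor(self, failure_type: str, index: int, fraction: float) -> "PenetrationSchedule":
        """Return a copy with one anchor's fraction replaced (sensitivity runs)."""
        anchors = list(self._anchors(failure_type))
        anchors[index] = (anchors[index][0], float(fraction))
        if failure_type == FAILURE_TAVR:
            return replace(self, tavr_failure=tuple(anchors))
        return replace(self, savr_failure=tuple(anchors))

    def to_dict(self) -> dict:
        return {
            "interpolation": "linear",
            "tavr_failure": [[y, f] for y, f in self.tavr_failure],
            "savr_failure": [[y, f] for y, f in self.savr_failure],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PenetrationSchedule":
        return cls(
            tuple((int(y), float(f)) for y, f in d["tavr_failure"]),
            tuple((int(y), float(f)) for y, f in d["savr_failure"]),
        )

    @classmethod
    def constant(cls, tavr_fraction: float, savr_fraction: float,
                 year: int = 2000) -> "PenetrationSchedule":
        return cls(((year, float(tavr_fraction)),), ((year, float(savr_fraction)),))


# ---------------------------------------------------------------------------
# redo surgery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedoSurgerySeries:
    """Annual counts of surgical redo procedures removed from the ViV pool.

    ``savr_after_savr`` is subtracted from SAVR-failure candidates,
    ``savr_after_tavr`` from TAVR-failure candidates. Years absent from a
    mapping count as zero.
    """

    savr_after_savr: dict[int, int] = field(default_factory=dict)
    savr_after_tavr: dict[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        for name, series in (("savr_after_savr", self.savr_after_savr),
                             ("savr_after_tavr", self.savr_after_tavr)):
            for y, c in series.items():
                if c < 0:
                    raise InvariantError(f"redo series {name} year {y} is negative")

    def count(self, kind: str, year: int) -> int:
        if kind == "savr_after_savr":
            return int(self.savr_after_savr.get(year, 0))
        if kind == "savr_after_tavr":
            return int(self.savr_after_tavr.get(year, 0))
        raise InvariantError(f"unknown redo kind {kind!r}")

    def to_dict(self) -> dict:
        def pack(series: dict[int, int]) -> dict:
            if not series:
                return {"start_year": 0, "counts": []}
            years = sorted(series)
            y0, y1 = years[0], years[-1]
            return {"start_year": y0, "counts": [int(series.get(y, 0)) for y in range(y0, y1 + 1)]}

        return {"savr_after_savr": pack(self.savr_after_savr),
                "savr_after_tavr": pack(self.savr_after_tavr)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RedoSurgerySeries":
        def unpack(p: Mapping) -> dict[int, int]:
            y0 = int(p["start_year"])
            return {y0 + i: int(c) for i, c in enumerate(p["counts"])}

        return cls(unpack(d["savr_after_savr"]), unpack(d["savr_after_tavr"]))


# ---------------------------------------------------------------------------
# top-level config
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Complete parameter set for one forecast scenario."""

    start_year: int
    end_year: int
    n_replicates: int
    master_seed: int
    tavr_volumes: AnnualVolumeSeries
    savr_volumes: AnnualVolumeSeries
    age_model: AgeDistribution
    risk_mix: RiskMixSchedule
    durability_models: dict[str, DurabilityMixture]
    survival_models: dict[str, SurvivalDistribution]
    penetration: PenetrationSchedule
    redo_series: RedoSurgerySeries
    max_attained_age: int = 100
    failure_year_rounding: str = "floor"  # or "half_up" (sensitivity switch)
    redo_before_penetration: bool = True
    tavr_series_includes_viv: bool = False

    # -- validation -------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        if self.start_year >= self.end_year:
            raise InvariantError("start_year must be < end_year")
        if self.n_replicates < 1:
            raise InvariantError("n_replicates must be >= 1")
        if self.master_seed < 0:
            raise InvariantError("master_seed must be a non-negative integer")
        if self.max_attained_age <= AGE_MAX:
            raise InvariantError("max_attained_age must exceed the oldest index age (95)")
        if self.failure_year_rounding not in ("floor", "half_up"):
            raise InvariantError("failure_year_rounding must be 'floor' or 'half_up'")
        self.age_model.validate()
        self.risk_mix.validate()
        self.penetration.validate()
        self.redo_series.validate()
        for key in (STRATUM_TAVR, STRATUM_SAVR_LT70, STRATUM_SAVR_GE70):
            if key not in self.durability_models:
                raise InvariantError(f"durability_models is missing stratum {key!r}")
        for m in self.durability_models.values():
            m.validate()
        for key in RISK_CLASSES:
            if key not in self.survival_models:
                raise InvariantError(f"survival_models is missing risk class {key!r}")
        for s in self.survival_models.values():
            s.validate()
        for proc, series in ((PROC_TAVR, self.tavr_volumes), (PROC_SAVR, self.savr_volumes)):
            if series.procedure != proc:
                raise InvariantError(f"{proc} volume series is tagged {series.procedure!r}")
            for year in self.years:
                if year not in series.counts:
                    raise InvariantError(f"{proc} volume series is missing year {year}")
                if series.counts[year] > 0 and not self.risk_mix.covers(proc, year):
                    raise InvariantError(f"risk mix does not cover {proc} seeding year {year}")
        return self

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "n_replicates": self.n_replicates,
            "master_seed": self.master_seed,
            "max_attained_age": self.max_attained_age,
            "failure_year_rounding": self.failure_year_rounding,
            "redo_before_penetration": self.redo_before_penetration,
            "tavr_series_includes_viv": self.tavr_series_includes_viv,
            "tavr_volumes": self.tavr_volumes.to_dict(),
            "savr_volumes": self.savr_volumes.to_dict(),
            "age_model": self.age_model.to_dict(),
            "risk_mix": self.risk_mix.to_dict(),
            "durability_models": {k: v.to_dict() for k, v in self.durability_models.items()},
            "survival_models": {k: v.to_dict() for k, v in self.survival_models.items()},
            "penetration": self.penetration.to_dict(),
            "redo_series": self.redo_series.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        try:
            cfg = cls(
                start_year=int(d["start_year"]),
                end_year=int(d["end_year"]),
                n_replicates=int(d["n_replicates"]),
                master_seed=int(d["master_seed"]),
                max_attained_age=int(d.get("max_attained_age", 100)),
                failure_year_rounding=str(d.get("failure_year_rounding", "floor")),
                redo_before_penetration=bool(d.get("redo_before_penetration", True)),
                tavr_series_includes_viv=bool(d.get("tavr_series_includes_viv", False)),
                tavr_volumes=AnnualVolumeSeries.from_dict(d["tavr_volumes"]),
                savr_volumes=AnnualVolumeSeries.from_dict(d["savr_volumes"]),
                age_model=AgeDistribution.from_dict(d["age_model"]),
                risk_mix=RiskMixSchedule.from_dict(d["risk_mix"]),
                durability_models={
                    str(k): DurabilityMixture.from_dict(v)
                    for k, v in d["durability_models"].items()
                },
                survival_models={
                    str(k): SurvivalDistribution.from_dict(v)
                    for k, v in d["survival_models"].items()
                },
                penetration=PenetrationSchedule.from_dict(d["penetration"]),
                redo_series=RedoSurgerySeries.from_dict(d["redo_series"]),
            )
        except KeyError as exc:
            raise ConfigError(f"configuration is missing key {exc.args[0]!r}") from exc
        return cfg.validate()

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    def sha256(self) -> str:
        return hashlib.sha256(self.dumps().encode()).hexdigest()


def _merge_over_defaults(base: dict, override: Mapping) -> dict:
    # top-level key replacement: a user-supplied sub-object (a distribution,
    # a schedule, a volume series) replaces the default one wholly, so a
    # partial distribution definition can never be silently mixed with default
    # parameters of a different family
    out = dict(base)
    out.update(override)
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML/JSON config file, filling unspecified fields from the
    packaged default scenario. An empty file yields the full default config."""
    text = Path(path).read_text()
    try:
        user = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    defaults = default_config().to_dict()
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration key {sorted(unknown)[0]!r}")
    return SimulationConfig.from_dict(_merge_over_defaults(defaults, user))


# ---------------------------------------------------------------------------
# packaged default scenario
# ---------------------------------------------------------------------------

def _data_csv(name: str, procedure: str) -> AnnualVolumeSeries:
    ref = resources.files("vivforecast.data").joinpath(name)
    with resources.as_file(ref) as p:
        return AnnualVolumeSeries.from_csv(p, procedure)


def default_volume_series() -> tuple[AnnualVolumeSeries, AnnualVolumeSeries]:
    """The packaged US-scale (TAVR, bioprosthetic SAVR) input series.

    TAVR: shipped registry-summary series 2012–2022, OLS line on the most
    recent six observed years, extrapolated back to 2007 and forward to 2035
    (earlier years are zero — TAVR was not commercially available). SAVR:
    literature values 1998–2011, 80% of total surgical AVR 2012–2020, and a
    constant 50,000/yr from 2021 to 2035.
    """
    tavr_obs = _data_csv("tavr_observed_us.csv", PROC_TAVR)
    tavr = build_tavr_series(tavr_obs.counts, back_to=2007, forward_to=2035)
    tavr = tavr.extended(1998, 2035, fill=0, provenance="assumed")

    pre = _data_csv("savr_bioprosthetic_1998_2011_us.csv", PROC_SAVR)
    total = _data_csv("savr_total_surgical_2012_2020_us.csv", PROC_SAVR)
    savr = build_savr_series(
        total_surgical=total.counts,
        bioprosthetic_fraction=0.80,
        pre_period=pre.counts,
        constant_from=2021,
        constant_value=50_000,
        end_year=2035,
    )
    return tavr, savr


def default_config() -> SimulationConfig:
    """The packaged US forecast scenario.

    Encodes the published model parameters: bimodal TAVR durability
    (20%: mean 4, SD 1.5; 80%: mean 11.5, SD 3.5), age-dependent SAVR
    durability (mean 10/SD 5 below age 70, mean 17/SD 5 at 70+),
    intermediate-high survival median 6/SD 2, SAVR risk mix 85% low / 15%
    intermediate-high, era-wise TAVR risk mix, ViV penetration 10%→60%
    (TAVR failures) and 60%→80% (SAVR failures) between 2022 and 2035, and a
    20-replicate ensemble over 1998–2035.

    Parameters the source model does not publish numerically — the low-risk
    survival curve, the age distribution, the redo-surgery series, and the
    registry volume tables — carry documented approximations (see the data
    CSV headers and docs/methods.md) and can be overridden via config.
    """
    tavr, savr = default_volume_series()

    risk_mix = RiskMixSchedule(
        (
            RiskMixEntry(PROC_SAVR, 1998, 2036, 0.85),
            # pre-commercial-era TAVR (trial patients) treated as all
            # intermediate-to-high risk, like 2014-2019
            RiskMixEntry(PROC_TAVR, 1998, 2014, 0.0),
            RiskMixEntry(PROC_TAVR, 2014, 2019, 0.0),
            RiskMixEntry(PROC_TAVR, 2019, 2024, 1.0 / 3.0),
            RiskMixEntry(PROC_TAVR, 2024, 2036, 0.5),
        )
    )

    durability = {
        STRATUM_TAVR: DurabilityMixture(
            (MixtureComponent(0.20, 4.0, 1.5), MixtureComponent(0.80, 11.5, 3.5))
        ),
        STRATUM_SAVR_LT70: DurabilityMixture.single(10.0, 5.0),
        STRATUM_SAVR_GE70: DurabilityMixture.single(17.0, 5.0),
    }

    survival = {
        RISK_INTERMEDIATE_HIGH: SurvivalDistribution("truncated_normal", 6.0, 2.0),
        # not published numerically; documented package assumption
        RISK_LOW: SurvivalDistribution("truncated_normal", 12.0, 4.0),
    }

    penetration = PenetrationSchedule(
        tavr_failure=((2022, 0.10), (2035, 0.60)),
        savr_failure=((2022, 0.60), (2035, 0.80)),
    )

    # documented package assumptions (counts are not published):
    # SAVR-after-SAVR redo held constant; SAVR-after-TAVR (surgical explant)
    # ramps up as the TAVR population ages, then plateaus.
    savr_after_savr = {y: 3000 for y in range(1998, 2036)}
    savr_after_tavr: dict[int, int] = {y: 0 for y in range(1998, 2015)}
    for y in range(2015, 2031):
        savr_after_tavr[y] = round(100 + (2000 - 100) * (y - 2015) / 15)
    for y in range(2031, 2036):
        savr_after_tavr[y] = 2000

    cfg = SimulationConfig(
        start_year=1998,
        end_year=2035,
        n_replicates=20,
        master_seed=20240710,
        tavr_volumes=tavr,
        savr_volumes=savr,
        age_model=AgeDistribution.discretized_normal(77.0, 7.0),
        risk_mix=risk_mix,
        durability_models=durability,
        survival_models=survival,
        penetration=penetration,
        redo_series=RedoSurgerySeries(savr_after_savr, savr_after_tavr),
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# degenerate scenario factory (oracle tests, examples)
# ---------------------------------------------------------------------------

def degenerate_config(
    tavr_cohorts: Mapping[int, int] | None = None,
    savr_cohorts: Mapping[int, int] | None = None,
    *,
    start_year: int = 2000,
    end_year: int = 2010,
    age: int = 75,
    tavr_durability: float = 5.0,
    savr_durability_lt70: float = 5.0,
    savr_durability_ge70: float = 5.0,
    survival_low: float = 10.0,
    survival_intermediate_high: float = 10.0,
    fraction_low_tavr: float = 0.0,
    fraction_low_savr: float = 0.0,
    penetration_tavr: float = 1.0,
    penetration_savr: float = 1.0,
    redo: RedoSurgerySeries | None = None,
    n_replicates: int = 1,
    master_seed: int = 0,
) -> SimulationConfig:
    """Build a fully point-mass scenario whose outcome is hand-computable.

    All patient-level distributions are point masses, so with penetration in
    {0, 1} the pipeline is deterministic and can be checked against a direct
    enumeration.
    """
    from .volumes import synthesize_scenario

    tavr, savr = synthesize_scenario(
        "tiny-deterministic",
        {
            "start_year": start_year,
            "end_year": end_year,
            "tavr_cohorts": dict(tavr_cohorts or {}),
            "savr_cohorts": dict(savr_cohorts or {}),
        },
    )
    cfg = SimulationConfig(
        start_year=start_year,
        end_year=end_year,
        n_replicates=n_replicates,
        master_seed=master_seed,
        tavr_volumes=tavr,
        savr_volumes=savr,
        age_model=AgeDistribution.point_mass(age),
        risk_mix=RiskMixSchedule(
            (
                RiskMixEntry(PROC_TAVR, start_year, end_year + 1, fraction_low_tavr),
                RiskMixEntry(PROC_SAVR, start_year, end_year + 1, fraction_low_savr),
            )
        ),
        durability_models={
            STRATUM_TAVR: DurabilityMixture.single(tavr_durability, 0.0),
            STRATUM_SAVR_LT70: DurabilityMixture.single(savr_durability_lt70, 0.0),
            STRATUM_SAVR_GE70: DurabilityMixture.single(savr_durability_ge70, 0.0),
        },
        survival_models={
            RISK_LOW: SurvivalDistribution("truncated_normal", survival_low, 0.0),
            RISK_INTERMEDIATE_HIGH: SurvivalDistribution(
                "truncated_normal", survival_intermediate_high, 0.0
            ),
        },
        penetration=PenetrationSchedule.constant(
            penetration_tavr, penetration_savr, year=start_year
        ),
        redo_series=redo or RedoSurgerySeries(),
    )
    return cfg.validate()
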