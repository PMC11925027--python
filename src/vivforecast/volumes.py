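"""Annual index-procedure volume series.

The forecast model is seeded from two annual volume series: native (index)
TAVR implants and bioprosthetic surgical AVR implants. Observed registry years
are kept as given; years outside the observed range are filled by ordinary
least-squares linear extrapolation (TAVR) or by literature values / a constant
assumption (SAVR). A synthetic-scenario generator provides fully artificial
series so every downstream stage is testable without external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PROC_TAVR = "TAVR"
PROC_SAVR = "SAVR"

#: Allowed per-year provenance tags.
PROVENANCE_TAGS = ("observed", "extrapolated", "assumed", "synthetic")

SCENARIO_KINDS = ("tiny-deterministic", "linear-growth", "us-scale")


class VolumeError(ValueError):
    """Raised for invalid volume-series construction."""


@dataclass(frozen=True)
class AnnualVolumeSeries:
    """Year-indexed procedure counts for one procedure class.

    Parameters
    ----------
    procedure:
        ``"TAVR"`` or ``"SAVR"`` (bioprosthetic surgical AVR).
    counts:
        Mapping year -> non-negative integer count. Years must be contiguous.
    provenance:
        Mapping year -> one of :data:`PROVENANCE_TAGS`.
    """

    procedure: str
    counts: dict[int, int] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.procedure not in (PROC_TAVR, PROC_SAVR):
            raise VolumeError(f"unknown procedure class {self.procedure!r}")
        years = sorted(self.counts)
        if not years:
            raise VolumeError("volume series must contain at least one year")
        if years != list(range(years[0], years[-1] + 1)):
            raise VolumeError(f"{self.procedure} series years are not contiguous")
        for y in years:
            c = self.counts[y]
            if int(c) != c or c < 0:
                raise VolumeError(
                    f"{self.procedure} count for {y} must be a non-negative integer, got {c!r}"
                )
            tag = self.provenance.get(y)
            if tag not in PROVENANCE_TAGS:
                raise VolumeError(f"{self.procedure} year {y} has invalid provenance {tag!r}")
        # normalise counts to plain ints
        object.__setattr__(self, "counts", {int(y): int(self.counts[y]) for y in years})
        object.__setattr__(self, "provenance", {int(y): self.provenance[y] for y in years})

    # -- access -----------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(self.counts)

    @property
    def first_year(self) -> int:
        return min(self.counts)

    @property
    def last_year(self) -> int:
        return max(self.counts)

    def __getitem__(self, year: int) -> int:
        return self.counts[year]

    def get(self, year: int, default: int = 0) -> int:
        return self.counts.get(year, default)

    def extended(self, start_year: int, end_year: int, fill: int = 0,
                 provenance: str = "assumed") -> "AnnualVolumeSeries":
        """Pad the series with ``fill`` so it covers [start_year, end_year]."""
        counts = dict(self.counts)
        prov = dict(self.provenance)
        for y in range(start_year, end_year + 1):
            if y not in counts:
                counts[y] = fill
                prov[y] = provenance
        return AnnualVolumeSeries(self.procedure, counts, prov)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        years = self.years
        return {
            "procedure": self.procedure,
            "start_year": years[0],
            "counts": [self.counts[y] for y in years],
            "provenance": [self.provenance[y] for y in years],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnnualVolumeSeries":
        y0 = int(d["start_year"])
        counts = {y0 + i: int(c) for i, c in enumerate(d["counts"])}
        prov = {y0 + i: p for i, p in enumerate(d["provenance"])}
        return cls(str(d["procedure"]), counts, prov)

    def to_frame(self) -> pd.DataFrame:
        years = self.years
        return pd.DataFrame(
            {
                "year": years,
                "count": [self.counts[y] for y in years],
                "provenance": [self.provenance[y] for y in years],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path_or_buf: str | Path | io.IOBase, procedure: str) -> "AnnualVolumeSeries":
        df = pd.read_csv(path_or_buf, comment="#")
        required = {"year", "count", "provenance"}
        if not required.issubset(df.columns):
            raise VolumeError(f"volume CSV must have columns {sorted(required)}")
        counts = dict(zip(df["year"].astype(int), df["count"].astype(int)))
        prov = dict(zip(df["year"].astype(int), df["provenance"].astype(str)))
        return cls(procedure, counts, prov)


def _round_count(x: float) -> int:
    """Round a fractional procedure count half-to-even and clamp at zero."""
    return int(max(0.0, np.round(x)))


def build_tavr_series(observed: Mapping[int, int], back_to: int, forward_to: int,
                      fit_window: tuple[int, int] | None = None) -> AnnualVolumeSeries:
    """Extend an observed annual TAVR series by OLS linear extrapolation.

    Observed years keep their observed values; years outside the observed range
    are filled from a straight line fitted to ``fit_window`` (default: the most
    recent six observed years), clamped at zero and rounded to integers.
    """
    obs_years = sorted(observed)
    if len(obs_years) < 2:
        raise VolumeError("need at least 2 observed TAVR years to extrapolate")
    if back_to > obs_years[0]:
        raise VolumeError(
            f"back_to={back_to} is after the first observed year {obs_years[0]}"
        )
    if forward_to < obs_years[-1]:
        raise VolumeError(
            f"forward_to={forward_to} is before the last observed year {obs_years[-1]}"
        )
    if fit_window is None:
        fit_years = obs_years[-6:]
    else:
        lo, hi = fit_window
        fit_years = [y for y in obs_years if lo <= y <= hi]
        if len(fit_years) < 2:
            raise VolumeError("fit_window must contain at least 2 observed years")
    x = np.asarray(fit_years, dtype=float)
    y = np.asarray([observed[yy] for yy in fit_years], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)

    counts: dict[int, int] = {}
    prov: dict[int, str] = {}
    for yr in range(back_to, forward_to + 1):
        if yr in observed:
            counts[yr] = int(observed[yr])
            prov[yr] = "observed"
        else:
            counts[yr] = _round_count(slope * yr + intercept)
            prov[yr] = "extrapolated"
    return AnnualVolumeSeries(PROC_TAVR, counts, prov)


def build_savr_series(total_surgical: Mapping[int, int],
                      bioprosthetic_fraction: float,
                      pre_period: Mapping[int, int],
                      constant_from: int,
                      constant_value: int,
                      end_year: int) -> AnnualVolumeSeries:
    """Assemble the bioprosthetic SAVR series from its three sources.

    ``pre_period`` years are literature bioprosthetic counts taken as given;
    ``total_surgical`` years are scaled by ``bioprosthetic_fraction``; all
    years from ``constant_from`` to ``end_year`` are held at
    ``constant_value``.
    """
    if not 0 < bioprosthetic_fraction <= 1:
        raise VolumeError("bioprosthetic_fraction must be in (0, 1]")
    if constant_from > end_year:
        raise VolumeError("constant_from must not exceed end_year")

    counts: dict[int, int] = {}
    prov: dict[int, str] = {}
    for yr, c in pre_period.items():
        counts[int(yr)] = int(c)
        prov[int(yr)] = "observed"
    for yr, total in total_surgical.items():
        yr = int(yr)
        if yr in counts:
            raise VolumeError(f"conflicting SAVR sources for year {yr}")
        counts[yr] = _round_count(bioprosthetic_fraction * total)
        prov[yr] = "observed"
    for yr in range(constant_from, end_year + 1):
        if yr in counts:
            raise VolumeError(f"conflicting SAVR sources for year {yr}")
        counts[yr] = int(constant_value)
        prov[yr] = "assumed"
    return AnnualVolumeSeries(PROC_SAVR, counts, prov)


def synthesize_scenario(kind: str, params: Mapping | None = None,
                        seed: int = 0) -> tuple[AnnualVolumeSeries, AnnualVolumeSeries]:
    """Generate a (TAVR, SAVR) volume-series pair for a named scenario.

    Kinds
    -----
    ``tiny-deterministic``
        Hand-countable cohorts (params ``tavr_cohorts`` / ``savr_cohorts``:
        mapping year -> count; ``start_year``/``end_year`` span), zeros
        elsewhere. For oracle tests.
    ``linear-growth``
        Straight-line series ``intercept + slope * (year - start_year)`` per
        procedure class, optionally with seeded Gaussian jitter
        (``noise_sd``), clamped at zero.
    ``us-scale``
        The packaged US-magnitude default trajectory: OLS-extrapolated TAVR
        from the shipped registry series and bioprosthetic SAVR constant at
        50,000 from 2021.
    """
    params = dict(params or {})
    if kind == "tiny-deterministic":
        start = int(params.get("start_year", 2000))
        end = int(params.get("end_year", 2010))
        tavr_cohorts = {int(y): int(c) for y, c in params.get("tavr_cohorts", {2000: 100}).items()}
        savr_cohorts = {int(y): int(c) for y, c in params.get("savr_cohorts", {}).items()}

        def mk(proc: str, cohorts: dict[int, int]) -> AnnualVolumeSeries:
            counts = {y: cohorts.get(y, 0) for y in range(start, end + 1)}
            prov = {y: "synthetic" for y in counts}
            return AnnualVolumeSeries(proc, counts, prov)

        return mk(PROC_TAVR, tavr_cohorts), mk(PROC_SAVR, savr_cohorts)

    if kind == "linear-growth":
        start = int(params.get("start_year", 2000))
        end = int(params.get("end_year", 2020))
        noise_sd = float(params.get("noise_sd", 0.0))
        rng = np.random.default_rng(seed)

        def mk(proc: str, intercept: float, slope: float) -> AnnualVolumeSeries:
            counts = {}
            for y in range(start, end + 1):
                val = intercept + slope * (y - start)
                if noise_sd > 0:
                    val += rng.normal(0.0, noise_sd)
                counts[y] = _round_count(val)
            return AnnualVolumeSeries(proc, counts, {y: "synthetic" for y in counts})

        tavr = mk(PROC_TAVR, float(params.get("tavr_intercept", 0.0)),
                  float(params.get("tavr_slope", 10.0)))
        savr = mk(PROC_SAVR, float(params.get("savr_intercept", 100.0)),
                  float(params.get("savr_slope", 0.0)))
        return tavr, savr

    if kind == "us-scale":
        # deterministic: mirrors the packaged default construction
        from . import config as _config

        return _config.default_volume_series()

    raise VolumeError(f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
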