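"""Replicate ensemble, headline summaries, and file outputs.

The ensemble repeats the single-replicate simulation ``n_replicates`` times
with independent seeds derived from the master seed and reports the per-year
sample mean and sample standard deviation (n - 1 denominator) of each ViV
category. Headline quantities mirror the forecast's standard read-outs: the
end-of-horizon total, the ViV share of all TAVR, and the year TAVR-in-TAVR
catches up with TAVR-in-SAVR.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import AnnualViVForecast, run_single_replicate
from .volumes import AnnualVolumeSeries


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-year ensemble mean and SD of each ViV category."""

    years: np.ndarray
    tavr_in_savr_mean: np.ndarray
    tavr_in_savr_sd: np.ndarray
    tavr_in_tavr_mean: np.ndarray
    tavr_in_tavr_sd: np.ndarray
    total_mean: np.ndarray
    total_sd: np.ndarray
    n_replicates: int
    master_seed: int

    def _index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} is outside the simulated horizon")
        return int(idx[0])

    def total_mean_at(self, year: int) -> float:
        return float(self.total_mean[self._index(year)])

    def total_sd_at(self, year: int) -> float:
        return float(self.total_sd[self._index(year)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "tinS_mean": self.tavr_in_savr_mean,
                "tinS_sd": self.tavr_in_savr_sd,
                "tinT_mean": self.tavr_in_tavr_mean,
                "tinT_sd": self.tavr_in_tavr_sd,
                "total_mean": self.total_mean,
                "total_sd": self.total_sd,
            }
        )


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Derive one independent replicate seed per run from the master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n_replicates)
    return [int(s) for s in state]


def summarize_replicates(forecasts: list[AnnualViVForecast], master_seed: int) -> EnsembleSummary:
    """Sample mean/SD (ddof=1) per year and category; SD is 0 for n = 1."""
    if not forecasts:
        raise ValueError("need at least one replicate forecast")
    years = forecasts[0].years
    for f in forecasts[1:]:
        if not np.array_equal(f.years, years):
            raise ValueError("replicate forecasts cover different horizons")
    tin_s = np.stack([f.tavr_in_savr for f in forecasts]).astype(float)
    tin_t = np.stack([f.tavr_in_tavr for f in forecasts]).astype(float)
    total = tin_s + tin_t
    n = len(forecasts)

    def sd(a: np.ndarray) -> np.ndarray:
        if n == 1:
            return np.zeros(a.shape[1])
        return a.std(axis=0, ddof=1)

    return EnsembleSummary(
        years=years.copy(),
        tavr_in_savr_mean=tin_s.mean(axis=0),
        tavr_in_savr_sd=sd(tin_s),
        tavr_in_tavr_mean=tin_t.mean(axis=0),
        tavr_in_tavr_sd=sd(tin_t),
        total_mean=total.mean(axis=0),
        total_sd=sd(total),
        n_replicates=n,
        master_seed=int(master_seed),
    )


def run_ensemble(config: SimulationConfig, progress=None) -> EnsembleSummary:
    """Run the configured number of replicates and summarise them.

    ``progress`` may be a callable taking (replicate_index, n_replicates),
    e.g. for CLI logging.
    """
    config.validate()
    seeds = replicate_seeds(config.master_seed, config.n_replicates)
    forecasts = []
    for i, seed in enumerate(seeds):
        forecasts.append(run_single_replicate(config, seed))
        if progress is not None:
            progress(i + 1, config.n_replicates)
    return summarize_replicates(forecasts, config.master_seed)


def viv_share(summary: EnsembleSummary, tavr_volumes: AnnualVolumeSeries, year: int,
              series_includes_viv: bool = False) -> float:
    """ViV fraction of all TAVR procedures performed in ``year``.

    By default the configured TAVR series is native (index) implants only, so
    "all TAVR" = native + ViV; with ``series_includes_viv`` the series is
    taken as the all-TAVR total and used as the denominator directly.
    """
    viv = summary.total_mean_at(year)
    if year not in tavr_volumes.counts:
        raise KeyError(f"year {year} missing from the TAVR volume series")
    native = tavr_volumes[year]
    denom = native if series_includes_viv else native + viv
    if denom <= 0:
        raise ZeroDivisionError(f"no TAVR procedures in year {year}")
    return float(viv / denom)


def crossover_year(summary: EnsembleSummary, threshold: float = 0.9) -> int | None:
    """First year whose mean TAVR-in-TAVR reaches ``threshold`` times the
    mean TAVR-in-SAVR. Years with zero mean TAVR-in-TAVR are not eligible;
    returns None if the ratio is never reached."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    for i, year in enumerate(summary.years):
        t = summary.tavr_in_tavr_mean[i]
        s = summary.tavr_in_savr_mean[i]
        if t > 0 and t >= threshold * s:
            return int(year)
    return None


@dataclass(frozen=True)
class HeadlineSummary:
    """Standard forecast read-outs derived from an ensemble."""

    end_year: int
    total_viv_end: float
    viv_share_end: float | None  # None when no TAVR at all in the end year
    crossover_year_near: int | None  # threshold 0.9 ("nearly match")
    crossover_year_strict: int | None  # threshold 1.0
    sd_total: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "end_year": self.end_year,
            "total_viv_end": self.total_viv_end,
            "viv_share_end": self.viv_share_end,
            "crossover_year_near": self.crossover_year_near,
            "crossover_year_strict": self.crossover_year_strict,
            "sd_total": {str(y): v for y, v in self.sd_total.items()},
        }


def compute_headline(summary: EnsembleSummary, tavr_volumes: AnnualVolumeSeries,
                     sd_years: tuple[int, ...] = (2020, 2035),
                     series_includes_viv: bool = False) -> HeadlineSummary:
    end_year = int(summary.years[-1])
    try:
        share = viv_share(summary, tavr_volumes, end_year, series_includes_viv)
    except ZeroDivisionError:
        share = None
    return HeadlineSummary(
        end_year=end_year,
        total_viv_end=summary.total_mean_at(end_year),
        viv_share_end=share,
        crossover_year_near=crossover_year(summary, 0.9),
        crossover_year_strict=crossover_year(summary, 1.0),
        sd_total={int(y): summary.total_sd_at(int(y))
                  for y in sd_years if summary.years[0] <= y <= end_year},
    )


def write_outputs(summary: EnsembleSummary, headline: HeadlineSummary,
                  out_dir: str | Path, config: SimulationConfig | None = None) -> list[Path]:
    """Write forecast.csv, headline.json and a run log; returns written paths.

    forecast.csv is byte-identical across reruns with the same config and
    master seed (float cells formatted with %.10g).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "forecast.csv"
        summary.to_frame().to_csv(csv_path, index=False, float_format="%.10g",
                                  lineterminator="\n")
        headline_path = out / "headline.json"
        headline_path.write_text(json.dumps(headline.to_dict(), indent=2) + "\n")
        log_path = out / "run_log.json"
        log = {
            "master_seed": summary.master_seed,
            "n_replicates": summary.n_replicates,
            "replicate_seeds": replicate_seeds(summary.master_seed, summary.n_replicates),
            "config_sha256": config.sha256() if config is not None else None,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "python_version": platform.python_version(),
        }
        log_path.write_text(json.dumps(log, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc
    return [csv_path, headline_path, log_path]
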