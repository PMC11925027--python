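"""Per-patient attribute samplers.

Each seeded patient gets an age at the index procedure, a surgical-risk
class, a valve durability time (mixture of normals truncated to positive
values) and a post-procedure survival time (truncated normal, capped so the
attained age never exceeds a configurable maximum). Samplers accept either a
scalar request or a vector ``size`` and are pure functions of the random
stream position and parameters.
"""

from __future__ import annotations

import numpy as np

from .config import (
    AGE_MAX,
    AGE_MIN,
    RISK_INTERMEDIATE_HIGH,
    RISK_LOW,
    STRATUM_SAVR_GE70,
    STRATUM_SAVR_LT70,
    STRATUM_TAVR,
    AgeDistribution,
    DurabilityMixture,
    RiskMixSchedule,
    SurvivalDistribution,
)
from .volumes import PROC_SAVR, PROC_TAVR


def sample_age(rng: np.random.Generator, dist: AgeDistribution,
               size: int | None = None) -> int | np.ndarray:
    """Draw integer ages in [60, 95] from the configured distribution."""
    ages = rng.choice(dist.support, size=size, p=dist.weights)
    if size is None:
        return int(ages)
    return ages.astype(np.int64)


def assign_risk_class(rng: np.random.Generator, year: int, procedure: str,
                      mix: RiskMixSchedule, size: int | None = None):
    """Bernoulli draw of the risk class for a patient seeded in ``year``.

    Returns ``"low"`` / ``"intermediate_high"`` for a scalar request, or a
    boolean ``is_low`` array for a vector request.
    """
    frac_low = mix.fraction_low(procedure, year)
    if size is None:
        return RISK_LOW if rng.random() < frac_low else RISK_INTERMEDIATE_HIGH
    return rng.random(size) < frac_low


def _truncated_normal(rng: np.random.Generator, means: np.ndarray,
                      sds: np.ndarray, n: int) -> np.ndarray:
    """Elementwise normal draws rejected-and-redrawn until strictly positive.

    ``sd == 0`` yields the (positive) mean exactly.
    """
    x = rng.normal(means, sds)
    bad = x <= 0.0
    while bad.any():
        idx = np.flatnonzero(bad)
        x[idx] = rng.normal(means[idx], sds[idx])
        bad = x <= 0.0
    return x


def _mixture_draw(rng: np.random.Generator, mixture: DurabilityMixture,
                  n: int, return_components: bool = False):
    cum = np.cumsum(mixture.weights)
    comp = np.searchsorted(cum, rng.random(n), side="right")
    comp = np.minimum(comp, len(cum) - 1)  # guard float round-off at u ~ 1
    vals = _truncated_normal(rng, mixture.means[comp], mixture.sds[comp], n)
    if return_components:
        return vals, comp
    return vals


def sample_durability(rng: np.random.Generator, procedure: str, age,
                      models: dict[str, DurabilityMixture],
                      size: int | None = None, return_components: bool = False):
    """Draw valve failure times (years post-index) for one seeding cohort.

    TAVR uses a single (bimodal by default) mixture; SAVR durability is
    age-dependent with separate strata below / at-or-above age 70. The
    component is chosen by weight first, then the normal draw is truncated to
    (0, inf) within that component.
    """
    scalar = size is None
    ages = np.atleast_1d(np.asarray(age, dtype=np.int64))
    n = 1 if scalar else int(size)
    if not scalar and ages.size == 1:
        ages = np.full(n, ages[0])
    if ages.size != n:
        raise ValueError("age must be scalar or of length `size`")

    if procedure == PROC_TAVR:
        if STRATUM_TAVR not in models:
            raise LookupError("no durability mixture for stratum 'TAVR'")
        out = _mixture_draw(rng, models[STRATUM_TAVR], n, return_components)
    elif procedure == PROC_SAVR:
        for key in (STRATUM_SAVR_LT70, STRATUM_SAVR_GE70):
            if key not in models:
                raise LookupError(f"no durability mixture for stratum {key!r}")
        vals = np.empty(n)
        comps = np.zeros(n, dtype=np.int64)
        lt70 = ages < 70
        for key, mask in ((STRATUM_SAVR_LT70, lt70), (STRATUM_SAVR_GE70, ~lt70)):
            m = int(mask.sum())
            if m:
                v, c = _mixture_draw(rng, models[key], m, return_components=True)
                vals[mask] = v
                comps[mask] = c
        out = (vals, comps) if return_components else vals
    else:
        raise LookupError(f"unknown procedure class {procedure!r}")

    if scalar:
        if return_components:
            return float(out[0][0]), int(out[1][0])
        return float(out[0])
    return out


def sample_survival(rng: np.random.Generator, risk, age,
                    models: dict[str, SurvivalDistribution],
                    size: int | None = None, max_attained_age: int = 100):
    """Draw post-procedure survival times (years), truncated > 0 and capped.

    ``risk`` is a risk-class string (scalar) or a boolean ``is_low`` array
    (vector). The cap enforces attained age ``age + survival <=
    max_attained_age`` — the minimal age dependence of survival.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    if scalar:
        is_low = np.array([risk == RISK_LOW])
    else:
        is_low = np.asarray(risk, dtype=bool)
        if is_low.size != n:
            raise ValueError("risk must have length `size`")
    ages = np.atleast_1d(np.asarray(age, dtype=np.int64))
    if ages.size == 1 and n > 1:
        ages = np.full(n, ages[0])

    for key in (RISK_LOW, RISK_INTERMEDIATE_HIGH):
        if key not in models:
            raise LookupError(f"no survival distribution for risk class {key!r}")
    low, ih = models[RISK_LOW], models[RISK_INTERMEDIATE_HIGH]
    means = np.where(is_low, low.median_years, ih.median_years)
    sds = np.where(is_low, low.sd_years, ih.sd_years)
    vals = _truncated_normal(rng, means, sds, n)
    vals = np.minimum(vals, max_attained_age - ages)
    if scalar:
        return float(vals[0])
    return vals


def truncated_mixture_cdf(mixture: DurabilityMixture, x) -> np.ndarray:
    """CDF of the sampler's durability law: each normal component truncated
    to (0, inf) separately, then mixed by weight. Reference for fidelity
    tests; requires all component SDs > 0."""
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for c in mixture.components:
        z0 = norm.cdf(0.0, loc=c.mean_years, scale=c.sd_years)
        fx = (norm.cdf(x, loc=c.mean_years, scale=c.sd_years) - z0) / (1.0 - z0)
        out += c.weight * np.clip(fx, 0.0, 1.0)
    return np.where(x <= 0, 0.0, out)
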