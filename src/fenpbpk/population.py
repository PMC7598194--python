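"""Virtual populations and geometric-mean aggregation.

A virtual population covers the demographics of a study (age, weight, sex)
and adds interindividual variability as log-normal multipliers on the
expression of the implemented enzymes/transporters (CYP3A4, CYP3A7, P-gp) and
on the unspecific hepatic clearance rate constant. Multipliers have mean 1 on
the natural scale; their coefficient of variation is configurable per
parameter. An "individual-patient" mode keeps demographics fixed and varies
only the elimination processes, which is how per-patient profile simulations
are aggregated.

Population profiles are summarized pointwise as geometric mean and geometric
standard deviation (zero concentrations, e.g. pre-dose points, are excluded
from the aggregation rather than offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import engine as _eng
from .engine import DoseEvent, PBPKModel, SimulationResult
from .physiology import Individual, build_individual

__all__ = ["PopulationSpec", "PopulationResult", "sample_population",
           "build_population_models", "simulate_population", "aggregate_geo",
           "DEFAULT_VARIABILITY"]

# Representative literature CVs for hepatic CYP3A4/CYP3A7/P-gp expression and
# for the (mechanistically unassigned) unspecific hepatic clearance.
DEFAULT_VARIABILITY = {"CYP3A4": 0.35, "CYP3A7": 0.45, "PGP": 0.6,
                       "unspecific_hepatic": 0.35}


@dataclass(frozen=True)
class PopulationSpec:
    """Demographics, variability and seed for one virtual population."""

    n: int = 100
    sex_ratio_female: float = 0.5
    age_range: tuple[float, float] = (20.0, 50.0)     # years (chronological)
    gestational_age: float = 40.0                     # weeks
    weight_cv: float = 0.12          # log-normal CV around the age-typical weight
    fixed_individual: Individual | None = None        # individual-patient mode
    variability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIABILITY))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if any(cv < 0 for cv in self.variability.values()):
            raise ValueError("CVs must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("infeasible age range")


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal multipliers with E[X] = 1 and the requested natural-scale CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def sample_population(spec: PopulationSpec
                      ) -> list[tuple[Individual, dict[str, float]]]:
    """Draw n individuals plus expression multipliers, reproducibly by seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    params = sorted(spec.variability)
    mults = {p: _lognormal_mean_one(rng, spec.variability[p], spec.n)
             for p in params}
    sexes = rng.random(spec.n) < spec.sex_ratio_female
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], spec.n)
    weight_noise = _lognormal_mean_one(rng, spec.weight_cv, spec.n)
    for i in range(spec.n):
        if spec.fixed_individual is not None:
            ind = spec.fixed_individual
        else:
            sex = "female" if sexes[i] else "male"
            ref = build_individual(sex, float(ages[i]), spec.gestational_age)
            ind = build_individual(sex, float(ages[i]), spec.gestational_age,
                                   body_weight=ref.body_weight * weight_noise[i])
        out.append((ind, {p: float(mults[p][i]) for p in params}))
    return out


def build_population_models(spec: PopulationSpec, metabolite: bool = True,
                            **kinetic_overrides) -> list[PBPKModel]:
    """Default fentanyl(+norfentanyl) model per sampled individual."""
    return [_eng.default_model(ind, metabolite=metabolite,
                               expression_multipliers=m, **kinetic_overrides)
            for ind, m in sample_population(spec)]


@dataclass
class PopulationResult:
    individuals: list[SimulationResult]
    time: np.ndarray
    geo_mean: dict[tuple[str, str], np.ndarray]
    geo_sd: dict[tuple[str, str], np.ndarray]
    failures: list[int] = field(default_factory=list)


def aggregate_geo(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise geometric mean and geometric SD over rows.

    geo_mean = exp(mean(ln x)), geo_sd = exp(sd(ln x)). Non-positive values
    (pre-dose zeros, censored points) are excluded pointwise with a warning;
    time points with no positive values yield NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (n_individuals, n_times) array")
    bad = x <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} non-positive values from "
                      "geometric aggregation", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(bad, np.nan, np.log(np.where(bad, 1.0, x)))
        mean = np.nanmean(logs, axis=0)
        counts = (~np.isnan(logs)).sum(axis=0)
        sd = np.nanstd(logs, axis=0, ddof=1)
    sd = np.where(counts > 1, sd, 0.0)
    return np.exp(mean), np.exp(sd)


def simulate_population(models: list[PBPKModel],
                        regimen: list[DoseEvent],
                        t_end: float,
                        t_eval_h: np.ndarray | None = None,
                        rtol: float = 1e-7,
                        atol: float = 1e-10,
                        **kwargs) -> PopulationResult:
    """Run one regimen over all individuals and aggregate geometrically.

    Individual integration failures are reported by index and skipped; the
    run continues with the remaining subjects.
    """
    if t_eval_h is None:
        t_eval_h = np.linspace(0.0, t_end, 241)
    results: list[SimulationResult] = []
    failures: list[int] = []
    for i, m in enumerate(models):
        try:
            results.append(_eng.simulate(m, regimen, t_end, t_eval_h=t_eval_h,
                                         rtol=rtol, atol=atol, **kwargs))
        except _eng.EngineError as exc:      # pragma: no cover - defensive
            warnings.warn(f"individual {i} failed: {exc}", stacklevel=2)
            failures.append(i)
    if not results:
        raise _eng.EngineError("every individual simulation failed")
    keys = results[0].conc.keys()
    geo_mean, geo_sd = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key in keys:
            stack = np.vstack([r.conc[key] for r in results])
            geo_mean[key], geo_sd[key] = aggregate_geo(stack)
    return PopulationResult(individuals=results, time=results[0].time,
                            geo_mean=geo_mean, geo_sd=geo_sd, failures=failures)
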