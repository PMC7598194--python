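"""Synthetic observed datasets and the study-regimen fixture library.

The fixture library transcribes the dosing regimens, demographics and
sampling sites of the clinical study arms used for adult model building and
pediatric evaluation (bolus injections 0.3-60 ug/kg, short infusions, 24-58 h
continuous infusions, loading + maintenance schemes). Observed concentrations
of those studies are external literature data and are not shipped; instead,
``generate_observed`` produces synthetic stand-ins by sampling a model
simulation at assay-like times, multiplying by log-normal noise and censoring
below the assay LLOQ. This closes the loop for parameter-recovery and
goodness-of-fit testing without any external download.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import engine as _eng
from .engine import DoseEvent, PBPKModel
from .evaluation import ObservedDataset
from .physiology import Individual, build_individual

__all__ = ["StudyFixture", "NoiseSpec", "list_studies", "make_fixture",
           "fixture_individual", "generate_observed"]


@dataclass(frozen=True)
class StudyFixture:
    study_id: str
    regimen: tuple[DoseEvent, ...]
    sampling_site: str                  # venous_plasma | arterial_plasma
    analytes: tuple[str, ...]
    demographics: dict = field(default_factory=dict)
    dataset: str = "e"                  # i = training, e = test, p = pediatric
    ddi: bool = False

    @property
    def t_infusion_end_h(self) -> float:
        return max(ev.time_start + ev.duration for ev in self.regimen)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal measurement noise plus LLOQ censoring."""

    times_h: tuple[float, ...]
    proportional_cv_log: float = 0.2    # SD of log-concentration
    lloq_ng_ml: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv_log < 0:
            raise ValueError("cv must be >= 0")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sampling times must be strictly increasing")


@functools.lru_cache(maxsize=None)
def _studies_table() -> pd.DataFrame:
    with resources.as_file(resources.files("fenpbpk.data").joinpath("studies.csv")) as p:
        return pd.read_csv(p, comment="#")


def list_studies() -> list[str]:
    return list(_studies_table()["study_id"])


def make_fixture(study_id: str) -> StudyFixture:
    """Regimen + demographics for one encoded study arm."""
    t = _studies_table()
    row = t[t["study_id"] == study_id]
    if row.empty:
        raise KeyError(f"unknown study id {study_id!r}; see list_studies()")
    r = row.iloc[0]
    events: list[DoseEvent] = []
    if pd.notna(r["bolus_dose"]):
        events.append(DoseEvent(
            analyte="fentanyl", time_start=0.0,
            duration=float(r["bolus_duration_min"]) / 60.0,
            amount=float(r["bolus_dose"]), per_kg=bool(int(r["bolus_per_kg"]))))
    if pd.notna(r["infusion_rate"]):
        dur = float(r["infusion_duration_h"])
        events.append(DoseEvent(
            analyte="fentanyl", time_start=0.0, duration=dur,
            amount=float(r["infusion_rate"]) * dur,
            per_kg=bool(int(r["infusion_per_kg"]))))
    demographics = {
        "n": int(r["n"]), "female_pct": float(r["female_pct"]),
        "age_years": float(r["age_years"]),
        "gestational_weeks": float(r["gestational_weeks"]),
        "weight_kg": float(r["weight_kg"]) if pd.notna(r["weight_kg"]) else None,
    }
    return StudyFixture(
        study_id=study_id, regimen=tuple(events),
        sampling_site=f"{r['site']}_plasma",
        analytes=tuple(str(r["analytes"]).split("+")),
        demographics=demographics, dataset=str(r["dataset"]),
        ddi=bool(int(r["ddi"])),
    )


def fixture_individual(fixture: StudyFixture, sex: str = "male") -> Individual:
    """Build the study's mean individual from its demographics."""
    d = fixture.demographics
    return build_individual(sex, d["age_years"], d["gestational_weeks"],
                            body_weight=d["weight_kg"])


def generate_observed(model: PBPKModel, fixture: StudyFixture,
                      noise: NoiseSpec, analyte: str | None = None,
                      t_end: float | None = None) -> ObservedDataset:
    """Simulate a fixture and emit a noised, LLOQ-censored observed dataset.

    With cv = 0 and no LLOQ the dataset equals the model prediction at the
    sampling times. Censored points are dropped (never reported as zero);
    an error is raised if censoring removes every point.
    """
    analyte = analyte or fixture.analytes[0]
    times = np.asarray(noise.times_h, dtype=float)
    if t_end is None:
        t_end = max(float(times[-1]), fixture.t_infusion_end_h)
    res = _eng.simulate(model, list(fixture.regimen), t_end,
                        t_eval_h=times, rtol=1e-8, atol=1e-11)
    conc = res.conc[(fixture.sampling_site, analyte)].copy()
    rng = np.random.default_rng(noise.seed)
    if noise.proportional_cv_log > 0:
        conc = conc * np.exp(rng.normal(0.0, noise.proportional_cv_log,
                                        conc.size))
    keep = conc > 0
    if noise.lloq_ng_ml is not None:
        keep &= conc >= noise.lloq_ng_ml
    if not keep.any():
        raise ValueError("all sampled points were censored below the LLOQ")
    return ObservedDataset(
        study_id=fixture.study_id, analyte=analyte,
        sampling_site=fixture.sampling_site,
        times=res.time[keep], conc=conc[keep], lloq=noise.lloq_ng_ml,
        demographics=dict(fixture.demographics),
    )
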