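"""Plain-text interfaces: observed-data CSV dialect, tidy result export,
scenario configuration documents.

Observed-dataset CSV columns: ``study_id, analyte, site, time_h, conc_ng_ml``
plus optional ``sd_ng_ml`` and ``lloq_ng_ml``. A scenario YAML document
describes an individual (or population), a dosing regimen and the simulation
horizon; ``run_scenario`` executes it end to end.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine as _eng
from .engine import DoseEvent
from .evaluation import ObservedDataset
from .physiology import build_individual
from .population import PopulationSpec, build_population_models, simulate_population

__all__ = ["read_observed_csv", "write_observed_csv", "write_result_csv",
           "load_scenario", "run_scenario"]


def write_observed_csv(datasets: list[ObservedDataset], path) -> None:
    rows = []
    for ds in datasets:
        for i, (t, c) in enumerate(zip(ds.times, ds.conc)):
            rows.append({
                "study_id": ds.study_id, "analyte": ds.analyte,
                "site": ds.sampling_site, "time_h": t, "conc_ng_ml": c,
                "sd_ng_ml": ds.sd[i] if ds.sd is not None else np.nan,
                "lloq_ng_ml": ds.lloq if ds.lloq is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observed_csv(path) -> list[ObservedDataset]:
    df = pd.read_csv(path)
    out = []
    for (sid, analyte, site), g in df.groupby(["study_id", "analyte", "site"],
                                              sort=False):
        g = g.sort_values("time_h")
        lloq = g["lloq_ng_ml"].dropna()
        sd = g["sd_ng_ml"].to_numpy() if g["sd_ng_ml"].notna().any() else None
        out.append(ObservedDataset(
            study_id=str(sid), analyte=str(analyte), sampling_site=str(site),
            times=g["time_h"].to_numpy(), conc=g["conc_ng_ml"].to_numpy(),
            sd=sd, lloq=float(lloq.iloc[0]) if not lloq.empty else None,
        ))
    return out


def write_result_csv(result, path) -> None:
    """Tidy export: time_h, site, analyte, conc_ng_ml."""
    rows = []
    for (site, analyte), series in result.conc.items():
        for t, c in zip(result.time, series):
            rows.append({"time_h": t, "site": site, "analyte": analyte,
                         "conc_ng_ml": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def _regimen_from_doc(doc: list[dict]) -> list[DoseEvent]:
    return [DoseEvent(analyte=d.get("analyte", "fentanyl"),
                      time_start=float(d.get("time_start_h", 0.0)),
                      duration=float(d.get("duration_h", 0.0)),
                      amount=float(d["amount"]),
                      per_kg=bool(d.get("per_kg", False)))
            for d in doc]


def load_scenario(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if "regimen" not in doc:
        raise ValueError("scenario needs a 'regimen' section")
    return doc


def run_scenario(path_or_doc):
    """Execute a scenario document; returns a simulation or population result."""
    doc = path_or_doc if isinstance(path_or_doc, dict) else load_scenario(path_or_doc)
    if "regimen" not in doc:
        raise ValueError("scenario needs a 'regimen' section")
    regimen = _regimen_from_doc(doc["regimen"])
    t_end = float(doc.get("t_end_h", 24.0))
    ind_doc = doc.get("individual", {})
    individual = build_individual(
        ind_doc.get("sex", "male"),
        float(ind_doc.get("age_years", 30.0)),
        float(ind_doc.get("gestational_weeks", 40.0)),
        body_weight=ind_doc.get("weight_kg"),
    )
    metabolite = bool(doc.get("metabolite", True))
    pop_doc = doc.get("population")
    if pop_doc:
        spec = PopulationSpec(
            n=int(pop_doc.get("n", 100)),
            fixed_individual=individual if pop_doc.get("fixed_demographics") else None,
            age_range=tuple(pop_doc.get("age_range",
                                        [individual.chronological_age] * 2)),
            gestational_age=individual.gestational_age,
            seed=int(pop_doc.get("seed", 0)),
        )
        models = build_population_models(spec, metabolite=metabolite)
        return simulate_population(models, regimen, t_end)
    model = _eng.default_model(individual, metabolite=metabolite)
    return _eng.simulate(model, regimen, t_end)
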