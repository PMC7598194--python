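"""Pediatric extrapolation of the evaluated adult model.

Scaling replaces the adult physiology with the target individual's
(volumes, flows, GFR, hematocrit, plasma AAG), multiplies CYP3A4/CYP3A7
hepatic levels by their ontogeny factors, applies the proteomics-derived
P-gp ontogeny, and rescales the unbound fentanyl fraction via the AAG ratio.
Two deliberate carry-overs from the adult model are surfaced in the scaling
report: the blood-to-plasma ratio stays at the adult 0.87 (no pediatric
measurement exists) and the unspecific hepatic clearance rate constant stays
at 1.46 /min at every age (its physiological identity, hence its ontogeny, is
unknown). Neonates who underwent abdominal surgery with raised
intraabdominal pressure can be given a metabolic clearance reduction that
scales all three hepatic pathways down by a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import compound as _cmp
from . import engine as _eng
from .engine import DoseEvent, PBPKModel
from .physiology import Individual

__all__ = ["ScalingReport", "scale_to_pediatric", "predict_clearance",
           "apply_surgery_reduction"]

UNSPECIFIC_K_ADULT = 1.46   # 1/min, age-independent by design
ADULT_B2P = 0.87            # age-independent by design (model limitation)


@dataclass(frozen=True)
class ScalingReport:
    age_years: float
    gestational_weeks: float
    postmenstrual_weeks: float
    body_weight_kg: float
    ontogeny: dict[str, float]          # protein -> factor applied
    fu_scaled: float
    fu_adult: float
    b2p: float = ADULT_B2P
    unspecific_k_unscaled: bool = True
    surgery_reduction_factor: float | None = None

    def __str__(self) -> str:   # structured text emission
        lines = [
            f"pediatric scaling target: {self.age_years:.3g} y chronological, "
            f"GA {self.gestational_weeks:.3g} wk (PMA {self.postmenstrual_weeks:.1f} wk), "
            f"{self.body_weight_kg:.3g} kg",
            "ontogeny factors: " + ", ".join(
                f"{k}={v:.3g}" for k, v in sorted(self.ontogeny.items())),
            f"unbound fraction: {self.fu_scaled:.3f} (adult {self.fu_adult:.3f})",
            f"blood-to-plasma ratio kept at adult value {self.b2p}",
            "unspecific hepatic clearance rate constant kept age-independent: "
            f"{self.unspecific_k_unscaled}",
        ]
        if self.surgery_reduction_factor is not None:
            lines.append("metabolic clearance reduction (abdominal surgery): "
                         f"{self.surgery_reduction_factor:.0%}")
        return "\n".join(lines)


def scale_to_pediatric(adult_model: PBPKModel, individual: Individual,
                       ) -> tuple[PBPKModel, ScalingReport]:
    """Scale an assembled adult model to a pediatric individual.

    Physiology is replaced; enzyme/transporter levels follow the ontogeny
    tables (they are part of the individual); fu is rescaled through the AAG
    ratio; all drug-dependent parameters stay at their adult values.
    """
    spec = adult_model.spec
    if not spec:
        raise _eng.EngineError("adult model carries no assembly spec")
    analytes = []
    for comp, _, procs in spec["analytes"]:
        kps = _cmp.compute_partition_set(comp, individual)
        analytes.append((comp, kps, procs))
    model = _eng.assemble_model(
        individual, analytes, interaction=spec["interaction"],
        expression_multipliers=spec["expression_multipliers"],
        unspecific_on_plasma=spec["unspecific_on_plasma"])
    fen = spec["analytes"][0][0]
    report = ScalingReport(
        age_years=individual.chronological_age,
        gestational_weeks=individual.gestational_age,
        postmenstrual_weeks=individual.postmenstrual_age,
        body_weight_kg=individual.body_weight,
        ontogeny={k: individual.enzyme_levels[k]
                  for k in ("CYP3A4", "CYP3A7", "PGP", "AAG")},
        fu_scaled=_cmp.unbound_plasma_fraction(fen, individual),
        fu_adult=fen.fu_adult,
    )
    return model, report


def apply_surgery_reduction(model: PBPKModel, factor: float) -> PBPKModel:
    """Reduce CYP3A4, CYP3A7 and unspecific hepatic clearance by ``factor``.

    Renal filtration is untouched. ``factor`` must lie in [0, 1); 0 returns
    an equivalent model.
    """
    if not 0.0 <= factor < 1.0:
        raise ValueError("surgery reduction factor must be in [0, 1)")
    return _eng.modified(model, surgery_factor=factor)


def predict_clearance(model: PBPKModel, regimen: list[DoseEvent],
                      t_end: float = 48.0, site: str = "venous_plasma",
                      extrapolation_warn: float = 0.2,
                      ) -> dict[str, float]:
    """Plasma clearance from a simulated profile: CL = Dose / AUC(0-inf).

    AUC is the trapezoidal AUC_last plus a log-linear tail extrapolation from
    the terminal slope. Returns absolute (mL/min) and weight-normalized
    (mL/min/kg) clearance; a warning flag is set when the extrapolated tail
    exceeds ``extrapolation_warn`` of the total AUC.
    """
    analyte = model.parent
    res = _eng.simulate(model, regimen, t_end, rtol=1e-8, atol=1e-11)
    c = res.conc[(site, analyte)]
    t = res.time
    auc_last = float(np.trapezoid(c, t))
    # terminal slope from the last decade of positive concentrations
    pos = c > 0
    tail = np.where(pos & (t > 0.7 * t[-1]))[0]
    auc_tail = 0.0
    if tail.size >= 3:
        slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
        if slope < 0:
            auc_tail = float(c[tail[-1]] / -slope)
    auc_inf = auc_last + auc_tail
    dose_ug = res.dose_parent_ug
    cl_ml_min = dose_ug / auc_inf * 1000.0 / 60.0   # ug / (ng/mL * h) -> mL/min
    out = {
        "CL_ml_min": cl_ml_min,
        "CL_ml_min_kg": cl_ml_min / model.body_weight,
        "AUC_inf_ng_h_ml": auc_inf,
        "extrapolated_fraction": auc_tail / auc_inf if auc_inf > 0 else 0.0,
    }
    if out["extrapolated_fraction"] > extrapolation_warn:
        out["warning"] = (f"AUC tail extrapolation is "
                          f"{out['extrapolated_fraction']:.0%} of AUC(0-inf); "
                          "extend t_end")
    return out
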