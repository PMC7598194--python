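"""Model-performance statistics and local sensitivity analysis.

The two headline statistics follow the Open Systems Pharmacology convention:

* MRD (mean relative deviation) of a predicted profile from observations,
  ``MRD = 10 ** sqrt(sum((log10 c_pred - log10 c_obs)^2) / k)``; 1 = perfect.
* GMFE (geometric mean fold error) of predicted/observed AUC ratios,
  ``GMFE = 10 ** (sum(|log10 r|) / m)``; 1 = perfect.

Both are computed on log10 concentrations, so they are invariant to the
concentration unit. 2-fold coverage is the percentage of predicted/observed
pairs within [1/k, k]. Local sensitivity S of the exposure to a parameter p
is the normalized finite-difference coefficient (dAUC/AUC)/(dp/p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine as _eng
from .engine import DoseEvent, PBPKModel, SimulationResult

__all__ = ["ObservedDataset", "GofSummary", "mrd", "gmfe", "fold_coverage",
           "predict_at", "gof_summary", "sensitivity"]


@dataclass
class ObservedDataset:
    """One observed concentration-time profile with assay metadata."""

    study_id: str
    analyte: str
    sampling_site: str                  # venous_plasma | arterial_plasma
    times: np.ndarray                   # h, strictly increasing
    conc: np.ndarray                    # ng/mL
    sd: np.ndarray | None = None
    lloq: float | None = None           # ng/mL
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")

    def quantifiable(self) -> np.ndarray:
        """Mask of points above LLOQ (and > 0)."""
        m = self.conc > 0
        if self.lloq is not None:
            m &= self.conc >= self.lloq
        return m


def predict_at(pred_times: np.ndarray, pred_conc: np.ndarray,
               obs_times: np.ndarray) -> np.ndarray:
    """Interpolate a prediction onto observed times, log-linear in conc."""
    pred_times = np.asarray(pred_times, dtype=float)
    pred_conc = np.asarray(pred_conc, dtype=float)
    pos = pred_conc > 0
    if pos.sum() < 2:
        raise ValueError("prediction has fewer than two positive points")
    logc = np.interp(obs_times, pred_times[pos], np.log(pred_conc[pos]))
    return np.exp(logc)


def mrd(pred_times: np.ndarray, pred_conc: np.ndarray,
        obs: ObservedDataset, lloq_substitute: bool = False) -> float:
    """Mean relative deviation of a prediction from one observed profile.

    Points below LLOQ are excluded by default; with ``lloq_substitute`` they
    enter as LLOQ/2.
    """
    mask = obs.quantifiable()
    o = obs.conc.copy()
    if lloq_substitute and obs.lloq is not None:
        below = (obs.conc > 0) & ~mask
        o[below] = obs.lloq / 2.0
        mask |= below
    if not mask.any():
        raise ValueError("no pairable observations above LLOQ")
    p = predict_at(pred_times, pred_conc, obs.times[mask])
    if np.any(p <= 0):
        raise ValueError("prediction is non-positive at observed times")
    d = np.log10(p) - np.log10(o[mask])
    return float(10.0 ** np.sqrt(np.mean(d * d)))


def gmfe(ratios) -> float:
    """Geometric mean fold error of predicted/observed ratios."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio list")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    return float(10.0 ** np.mean(np.abs(np.log10(r))))


def fold_coverage(pairs, k: float = 2.0) -> float:
    """Percent of (predicted, observed) pairs with ratio within [1/k, k]."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("empty pair list")
    pred, obs = arr[:, 0], arr[:, 1]
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("pairs must be positive")
    r = pred / obs
    return float(100.0 * np.mean((r >= 1.0 / k) & (r <= k)))


@dataclass
class GofSummary:
    per_profile: pd.DataFrame          # study_id, analyte, mrd, auc_ratio
    gmfe_auc: float
    pct_within_2fold_conc: float
    pct_within_2fold_auc: float
    n_profiles: int
    n_concentrations: int


def gof_summary(predictions: list[tuple[np.ndarray, np.ndarray]],
                observations: list[ObservedDataset]) -> GofSummary:
    """Goodness-of-fit statistics over paired prediction/observation profiles."""
    if len(predictions) != len(observations):
        raise ValueError("predictions and observations must align")
    rows = []
    conc_pairs = []
    for (pt, pc), obs in zip(predictions, observations):
        mask = obs.quantifiable()
        p = predict_at(pt, pc, obs.times[mask])
        o = obs.conc[mask]
        conc_pairs += list(zip(p, o))
        auc_pred = np.trapezoid(predict_at(pt, pc, obs.times[mask]), obs.times[mask])
        auc_obs = np.trapezoid(o, obs.times[mask])
        rows.append({
            "study_id": obs.study_id, "analyte": obs.analyte,
            "mrd": mrd(pt, pc, obs),
            "auc_ratio": auc_pred / auc_obs if auc_obs > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    auc_pairs = [(r["auc_ratio"], 1.0) for r in rows if np.isfinite(r["auc_ratio"])]
    return GofSummary(
        per_profile=df,
        gmfe_auc=gmfe(df["auc_ratio"].dropna()),
        pct_within_2fold_conc=fold_coverage(conc_pairs),
        pct_within_2fold_auc=fold_coverage(auc_pairs),
        n_profiles=len(rows), n_concentrations=len(conc_pairs),
    )


def sensitivity(model: PBPKModel, regimen: list[DoseEvent], parameters,
                delta: float = 0.1, t_end: float = 48.0,
                site: str = "venous_plasma", analyte: str | None = None,
                modifier=None) -> dict[str, float]:
    """Local sensitivity of AUC to relative single-parameter changes.

    ``parameters`` maps override names (as accepted by
    :func:`fenpbpk.engine.modified`) to their current values; each is
    perturbed to p (1 +/- delta) and the central-difference coefficient
    S = (AUC(+) - AUC(-)) / (2 delta AUC0) reported, which converges to the
    exact normalized derivative as delta shrinks. ``modifier(model, name,
    value)`` may replace the default rebuild for custom model families.
    """
    analyte = analyte or model.parent
    if modifier is None:
        modifier = lambda m, name, value: _eng.modified(m, **{name: value})
    base = _eng.simulate(model, regimen, t_end, rtol=1e-8, atol=1e-11)
    auc0 = _eng.summary_pk(base, site, analyte)["AUC_last"]
    out = {}
    for name, value in parameters.items():
        aucs = []
        for sign in (+1.0, -1.0):
            m2 = modifier(model, name, value * (1.0 + sign * delta))
            res = _eng.simulate(m2, regimen, t_end, rtol=1e-8, atol=1e-11)
            aucs.append(_eng.summary_pk(res, site, analyte)["AUC_last"])
        out[name] = (aucs[0] - aucs[1]) / (2.0 * delta * auc0)
    return out
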