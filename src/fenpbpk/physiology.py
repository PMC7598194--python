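"""Reference anatomy/physiology and ontogeny.

This module builds :class:`Individual` objects — the system-dependent half of a
whole-body PBPK model — from a versioned physiology snapshot shipped as CSV
tables (``data/organs.csv``, ``data/maturation.csv``, ``data/ontogeny.csv``).
The snapshot covers a 73-kg adult male reference and age scaling from preterm
neonates (24 weeks postmenstrual age) to 80-year-old adults.

Conventions
-----------
* Postmenstrual age (PMA, weeks) = gestational age + 52.14 x chronological age
  in years; PMA is the maturation clock for every age-dependent quantity.
* Ontogeny factors are fractions of the adult level (adult = 1.0 for CYP3A4,
  P-gp and AAG; CYP3A7 exceeds 1 before and around term birth).
* Glomerular filtration matures with PMA following a sigmoid Hill function and
  scales allometrically with body weight.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TissueComposition",
    "OrganSpec",
    "Individual",
    "build_individual",
    "ontogeny_factor",
    "scale_fu",
    "ADULT_REFERENCE_AGE",
    "ADULT_REFERENCE_WEIGHT",
    "ADULT_AAG_G_L",
]

# Adult reference anchors of the snapshot.
ADULT_REFERENCE_AGE = 30.0      # years
ADULT_REFERENCE_WEIGHT = 73.0   # kg
ADULT_AAG_G_L = 0.80            # alpha-1-acid glycoprotein plasma conc., g/L
ADULT_GFR_ML_MIN = 112.0        # glomerular filtration rate, mL/min
ADULT_CO_L_MIN = 5.6            # cardiac output (blood), L/min
PLASMA_PH = 7.4
WEEKS_PER_YEAR = 52.14

# GFR maturation: sigmoid in PMA (Hill coefficient / half-maturation PMA are the
# published maturation-curve shape), allometric body-weight scaling.
_GFR_HILL = 3.4
_GFR_PMA50 = 47.7  # weeks

_BLOOD_POOLS = ("arterial_blood", "venous_blood", "portal_vein")
# Organs draining into the portal vein (the liver receives their venous outflow).
PORTAL_ORGANS = ("stomach", "small_intestine", "large_intestine", "pancreas",
                 "spleen", "gallbladder")

_PMA_MIN = 24.0
_AGE_MAX_YEARS = 80.0


@dataclass(frozen=True)
class TissueComposition:
    """Tissue composition inputs for partition-coefficient calculations."""

    f_water_ec: float
    f_water_ic: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    conc_acidic_phospholipid: float  # mg/g tissue
    pH_ic: float = 7.0
    pH_p: float = PLASMA_PH
    albumin_ratio: float = 0.5       # interstitial:plasma binding-protein ratio
    lipoprotein_ratio: float = 0.5


@dataclass(frozen=True)
class OrganSpec:
    name: str
    total_volume: float          # L, including regional blood
    vascular_fraction: float
    interstitial_fraction: float
    cellular_fraction: float
    blood_flow: float            # L/min of whole blood
    composition: TissueComposition | None
    pgp_destination: str = "none"   # none | excreta | vascular

    def __post_init__(self) -> None:
        s = self.vascular_fraction + self.interstitial_fraction + self.cellular_fraction
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: sub-compartment fractions sum to {s}, not 1")


@dataclass(frozen=True)
class Individual:
    """Anatomy/physiology of one virtual subject."""

    sex: str
    chronological_age: float     # years
    gestational_age: float       # weeks
    body_weight: float           # kg
    height: float                # cm
    hematocrit: float
    GFR: float                   # mL/min
    cardiac_output: float        # L/min whole blood
    plasma_AAG: float            # g/L
    organs: tuple[OrganSpec, ...]
    enzyme_levels: dict[str, float] = field(default_factory=dict)

    @property
    def postmenstrual_age(self) -> float:
        """PMA in weeks."""
        return self.gestational_age + self.chronological_age * WEEKS_PER_YEAR

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def aag_ratio(self) -> float:
        """Plasma AAG relative to the adult reference."""
        return self.plasma_AAG / ADULT_AAG_G_L


def _data_path(name: str):
    return resources.files("fenpbpk.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def _organs_table() -> pd.DataFrame:
    with resources.as_file(_data_path("organs.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def _maturation_table() -> pd.DataFrame:
    with resources.as_file(_data_path("maturation.csv")) as p:
        return pd.read_csv(p, comment="#").sort_values("pma_weeks").reset_index(drop=True)


@functools.lru_cache(maxsize=None)
def _ontogeny_table() -> pd.DataFrame:
    with resources.as_file(_data_path("ontogeny.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def _enzyme_table() -> pd.DataFrame:
    with resources.as_file(_data_path("enzymes.csv")) as p:
        return pd.read_csv(p, comment="#")


def enzyme_reference_concentrations() -> dict[tuple[str, str], float]:
    """(protein, organ) -> effective adult concentration in umol/L cell volume."""
    t = _enzyme_table()
    return {(r.protein, r.organ): float(r.ref_conc_umol_l) for r in t.itertuples()}


def _interp_clamped(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    return float(np.interp(x, xs, ys))


def _maturation_value(pma: float, column: str) -> float:
    t = _maturation_table()
    return _interp_clamped(pma, t["pma_weeks"].to_numpy(), t[column].to_numpy())


def ontogeny_factor(protein: str, postmenstrual_age: float) -> float:
    """Protein abundance as a fraction of the adult level.

    Piecewise-linear in PMA between snapshot knots, clamped outside the knot
    range (so adults of any age get exactly the adult level).
    """
    if postmenstrual_age < _PMA_MIN:
        raise ValueError(f"postmenstrual age {postmenstrual_age} wk below supported "
                         f"minimum of {_PMA_MIN} wk")
    t = _ontogeny_table()
    sub = t[t["protein"] == protein]
    if sub.empty:
        raise KeyError(f"unknown protein {protein!r}; snapshot has "
                       f"{sorted(t['protein'].unique())}")
    sub = sub.sort_values("pma_weeks")
    return _interp_clamped(postmenstrual_age, sub["pma_weeks"].to_numpy(),
                           sub["factor"].to_numpy())


def scale_fu(fu_adult: float, aag_ratio: float) -> float:
    """Scale the unbound plasma fraction by the pediatric:adult AAG ratio.

    Single-binding-protein scaling: fu_ped = 1 / (1 + (1 - fu_adult)/fu_adult * ratio).
    At ratio 1 the adult value is returned exactly; the result decreases
    monotonically as the AAG ratio rises.
    """
    if not 0.0 < fu_adult <= 1.0:
        raise ValueError("fu_adult must be in (0, 1]")
    if aag_ratio <= 0.0:
        raise ValueError("AAG ratio must be positive")
    return 1.0 / (1.0 + (1.0 - fu_adult) / fu_adult * aag_ratio)


def gfr_ml_min(body_weight: float, pma_weeks: float) -> float:
    """Glomerular filtration rate with sigmoid PMA maturation and allometry."""
    mat = pma_weeks**_GFR_HILL / (pma_weeks**_GFR_HILL + _GFR_PMA50**_GFR_HILL)
    return ADULT_GFR_ML_MIN * (body_weight / ADULT_REFERENCE_WEIGHT) ** 0.75 * mat


def build_individual(sex: str,
                     chronological_age: float,
                     gestational_age: float = 40.0,
                     body_weight: float | None = None,
                     height: float | None = None) -> Individual:
    """Construct an :class:`Individual` from the physiology snapshot.

    Organ volumes scale weight-proportionally from the adult reference, with
    age-dependent multipliers for organs whose body share changes during
    growth (brain, liver, kidney, fat, muscle, skin, blood); blood-flow
    fractions are age-adjusted and renormalized to the (allometric) cardiac
    output. The result is a pure function of its arguments.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if chronological_age < 0:
        raise ValueError("chronological age must be >= 0")
    if not 24.0 <= gestational_age <= 44.0:
        raise ValueError("gestational age must be within 24-44 weeks")
    if chronological_age > _AGE_MAX_YEARS:
        raise ValueError(f"age {chronological_age} y outside supported range "
                         f"(24 wk PMA to {_AGE_MAX_YEARS} y)")
    pma = gestational_age + chronological_age * WEEKS_PER_YEAR
    if pma < _PMA_MIN:
        raise ValueError(f"postmenstrual age {pma:.1f} wk below supported 24 wk")

    if body_weight is None:
        body_weight = _maturation_value(pma, "body_weight_kg")
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    if height is None:
        height = _maturation_value(pma, "height_cm")
    hct = _maturation_value(pma, "hematocrit")

    w_scale = body_weight / ADULT_REFERENCE_WEIGHT
    co = ADULT_CO_L_MIN * w_scale**0.75
    gfr = gfr_ml_min(body_weight, pma)

    t = _organs_table()
    vol_mult_cols = {"brain": "brain_vol_mult", "liver": "liver_vol_mult",
                     "kidney": "kidney_vol_mult", "fat": "fat_vol_mult",
                     "muscle": "muscle_vol_mult", "skin": "skin_vol_mult"}
    flow_mult_cols = {"brain": "brain_flow_mult", "kidney": "kidney_flow_mult"}
    blood_mult = _maturation_value(pma, "blood_vol_mult")

    # Raw scaled volumes, then renormalize so the total body volume share of the
    # snapshot is preserved at every age.
    raw_vols: dict[str, float] = {}
    adult_total = float(t["total_volume_l"].sum())
    for r in t.itertuples():
        mult = blood_mult if r.name in _BLOOD_POOLS else 1.0
        if r.name in vol_mult_cols:
            mult = _maturation_value(pma, vol_mult_cols[r.name])
        raw_vols[r.name] = float(r.total_volume_l) * w_scale * mult
    norm = (adult_total * w_scale) / sum(raw_vols.values())
    vols = {k: v * norm for k, v in raw_vols.items()}

    # Systemic flow fractions (everything except the lung, which carries the
    # full cardiac output in series), renormalized to 1.
    fracs: dict[str, float] = {}
    for r in t.itertuples():
        if r.name in _BLOOD_POOLS or r.name == "lung":
            continue
        f = float(r.flow_frac)
        if r.name in flow_mult_cols:
            f *= _maturation_value(pma, flow_mult_cols[r.name])
        fracs[r.name] = f
    total_frac = sum(fracs.values())
    fracs = {k: v / total_frac for k, v in fracs.items()}

    organs = []
    for r in t.itertuples():
        if r.name in _BLOOD_POOLS:
            comp = None
            flow = 0.0
            fv, fi, fc = 1.0, 0.0, 0.0
        else:
            comp = TissueComposition(
                f_water_ec=float(r.f_water_ec),
                f_water_ic=float(r.f_water_ic),
                f_neutral_lipid=float(r.f_neutral_lipid),
                f_neutral_phospholipid=float(r.f_neutral_phospholipid),
                conc_acidic_phospholipid=float(r.acidic_phospholipid_mg_g),
                pH_ic=float(r.ph_ic),
                albumin_ratio=float(r.albumin_ratio),
                lipoprotein_ratio=float(r.lipoprotein_ratio),
            )
            fv = float(r.frac_vascular)
            fi = float(r.frac_interstitial)
            fc = 1.0 - fv - fi
            flow = co if r.name == "lung" else fracs[r.name] * co
        organs.append(OrganSpec(
            name=r.name, total_volume=vols[r.name],
            vascular_fraction=fv, interstitial_fraction=fi, cellular_fraction=fc,
            blood_flow=flow, composition=comp,
            pgp_destination=str(r.pgp_destination),
        ))

    enzyme_levels = {p: ontogeny_factor(p, pma)
                     for p in ("CYP3A4", "CYP3A7", "PGP", "AAG")}
    plasma_aag = ADULT_AAG_G_L * enzyme_levels["AAG"]

    return Individual(
        sex=sex, chronological_age=chronological_age,
        gestational_age=gestational_age, body_weight=float(body_weight),
        height=float(height), hematocrit=hct, GFR=gfr, cardiac_output=co,
        plasma_AAG=plasma_aag, organs=tuple(organs), enzyme_levels=enzyme_levels,
    )
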