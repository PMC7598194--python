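"""Tissue partition coefficients and cellular permeability.

Two partition-coefficient methods are provided, dispatched per compound:

* ``rodgers_rowland`` — mechanistic method for ionizable drugs in which a
  moderate-to-strong base (pKa > 7) distributes into tissue water, neutral
  lipid/phospholipid, and — as the dominant term for cations — electrostatic
  association with acidic phospholipids. The acidic-phospholipid association
  constant is not an input: it is back-calculated from the measured
  blood-to-plasma ratio via erythrocyte partitioning, the method's standard
  route.
* ``schmitt`` — membrane-affinity based method in which the ionized species
  retains a small fraction of the neutral species' membrane affinity; suited
  to compounds without a measured blood-cell partition (here the metabolite).

Permeability into the cellular space uses a lipophilicity/size relation with a
charge-dependent variant that down-weights the membrane permeability of the
ionized fraction; a fixed measured/calculated value overrides the formula.
"""

from __future__ import annotations

import math

from .physiology import TissueComposition, PLASMA_PH

__all__ = ["rodgers_rowland_kpu", "schmitt_kpu", "acidic_phospholipid_ka",
           "permeability_cm_min", "CELL_SURFACE_PER_VOLUME"]

# Erythrocyte composition used to back-calculate the acidic-phospholipid
# association constant from the blood-to-plasma ratio.
_RBC_F_IW = 0.603
_RBC_F_NL = 0.0017
_RBC_F_NP = 0.0029
_RBC_AP_MG_G = 0.5
_RBC_PH = 7.22

# Specific cell surface area per cellular volume (cm^2 per cm^3); with the
# permeability P in cm/min this makes the cellular exchange conductance
# PS [L/min] = 1000 * P * V_cell [L].
CELL_SURFACE_PER_VOLUME = 1000.0

# Neutral-lipid partitioning in adipose uses a vegetable-oil:water coefficient
# (log Pvo = 1.115 logP - 1.35); elsewhere octanol:water is used.
_VO_SLOPE, _VO_INTERCEPT = 1.115, -1.35

# Membrane affinity retained by the cationic species (Schmitt-type and
# charge-dependent permeability).
_ION_MEMBRANE_FACTOR = 0.05


def _base_ion(pka: float, ph: float) -> float:
    """10^(pKa - pH): cation:neutral ratio of a monoprotic base."""
    return 10.0 ** (pka - ph)


def acidic_phospholipid_ka(pka: float, logp: float, fu: float, b2p: float,
                           hematocrit: float = 0.45) -> float:
    """Association constant to acidic phospholipids from the B:P ratio.

    Erythrocyte:plasma-water partitioning Kpu_BC = (B2P - (1 - hct))/(hct * fu)
    is decomposed into water, neutral-lipid and acidic-phospholipid terms; the
    last is solved for Ka.
    """
    kpu_bc = (b2p - (1.0 - hematocrit)) / (hematocrit * fu)
    p = 10.0 ** logp
    x = 1.0 + _base_ion(pka, _RBC_PH)
    y = 1.0 + _base_ion(pka, PLASMA_PH)
    water = _RBC_F_IW * x / y
    lipid = (p * _RBC_F_NL + (0.3 * p + 0.7) * _RBC_F_NP) / y
    ka = (kpu_bc - water - lipid) * y / (_RBC_AP_MG_G * (x - 1.0))
    if ka <= 0.0:
        raise ValueError(
            "blood-to-plasma ratio too low to support acidic-phospholipid "
            "association; check B2P/fu/hematocrit inputs")
    return ka


def rodgers_rowland_kpu(comp: TissueComposition, pka: float, logp: float,
                        ka_ap: float, adipose: bool = False) -> float:
    """Unbound tissue:plasma partition coefficient for a moderate-strong base."""
    p = 10.0 ** logp
    p_nl = 10.0 ** (_VO_SLOPE * logp + _VO_INTERCEPT) if adipose else p
    x = 1.0 + _base_ion(pka, comp.pH_ic)
    y = 1.0 + _base_ion(pka, comp.pH_p)
    kpu = (comp.f_water_ec
           + comp.f_water_ic * x / y
           + ka_ap * comp.conc_acidic_phospholipid * (x - 1.0) / y
           + (p_nl * comp.f_neutral_lipid + (0.3 * p + 0.7) * comp.f_neutral_phospholipid) / y)
    return kpu


def schmitt_kpu(comp: TissueComposition, pka: float, logp: float) -> float:
    """Unbound tissue:plasma partition coefficient, membrane-affinity based.

    Phospholipid membranes take both species (the cation with a 20-fold
    handicap on the neutral affinity 10^logP); neutral storage lipid takes
    only the neutral species, as in the ion-partitioning treatment of strong
    bases.
    """
    k_n = 10.0 ** logp
    x = 1.0 + _base_ion(pka, comp.pH_ic)
    y = 1.0 + _base_ion(pka, comp.pH_p)
    f_neutral_ic = 1.0 / x
    k_mem = k_n * (f_neutral_ic + _ION_MEMBRANE_FACTOR * (1.0 - f_neutral_ic))
    f_membrane = (comp.f_neutral_phospholipid
                  + comp.conc_acidic_phospholipid / 1000.0)
    return (comp.f_water_ec
            + (x / y) * (comp.f_water_ic + f_membrane * k_mem)
            + k_n * comp.f_neutral_lipid / y)


def permeability_cm_min(method: str, mw: float, logp: float, pka: float | None,
                        fixed: float | None = None) -> float:
    """Permeability into the cellular space (cm/min).

    ``standard``: log10 P = 0.6 logP - 0.4 log10 MW - 1.0 (monotone in
    lipophilicity, weakly decreasing in size). ``charge_dependent_schmitt``:
    the ionized fraction at plasma pH permeates with a 20-fold handicap.
    ``fixed``: the supplied value is returned verbatim.
    """
    if fixed is not None:
        return float(fixed)
    if method == "fixed":
        raise ValueError("fixed permeability requested but no value supplied")
    p = 10.0 ** (0.6 * logp - 0.4 * math.log10(mw) - 1.0)
    if method == "standard":
        return p
    if method == "charge_dependent_schmitt":
        if pka is None:
            return p
        f_neutral = 1.0 / (1.0 + _base_ion(pka, PLASMA_PH))
        return p * (f_neutral + _ION_MEMBRANE_FACTOR * (1.0 - f_neutral))
    raise ValueError(f"unknown permeability method {method!r}")
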