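"""Drug-dependent parameters for fentanyl and norfentanyl.

The loaders reproduce the final parent-metabolite model parameter set exactly:
physicochemistry (MW, basic pKa, logP), plasma binding (fu), blood-to-plasma
ratio, the glomerular-filtration multiplier, and the process kinetics
(CYP3A4/CYP3A7 Michaelis-Menten conversion of fentanyl to norfentanyl, the
first-order unspecific hepatic clearance acting on liver plasma, and P-gp
efflux). Distribution inputs (tissue partition coefficients, cellular
permeability) are computed from these parameters plus the individual's tissue
composition. Compounds can also be defined in YAML documents, so additional
analytes need no code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from . import partition as _pt
from .physiology import Individual, scale_fu

__all__ = [
    "CompoundParams", "ProcessKinetics", "InteractionParams", "PartitionSet",
    "load_fentanyl", "load_norfentanyl", "load_voriconazole_interaction",
    "compute_partition_set", "compute_permeability", "unbound_plasma_fraction",
    "compound_from_yaml", "compound_to_yaml",
]


@dataclass(frozen=True)
class CompoundParams:
    name: str
    MW: float                       # g/mol
    pKa_base: float
    logP: float
    fu_adult: float                 # fraction
    B2P: float                      # blood:plasma concentration ratio
    GFR_fraction: float             # multiplier on GFR-driven renal filtration
    partition_method: str = "rodgers_rowland"   # or "schmitt"
    permeability_method: str = "charge_dependent_schmitt"  # "standard" | "fixed"
    permeability_fixed: float | None = None     # cm/min

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError("MW must be positive")
        if not 0 < self.fu_adult <= 1:
            raise ValueError("fu_adult must be in (0, 1]")
        if self.B2P <= 0:
            raise ValueError("B2P must be positive")
        if self.GFR_fraction < 0:
            raise ValueError("GFR_fraction must be >= 0")


@dataclass(frozen=True)
class ProcessKinetics:
    """One elimination/transport process.

    Michaelis-Menten processes carry ``Km`` (umol/L) and ``kcat`` (1/min);
    the first-order unspecific hepatic process carries only ``k`` (1/min).
    """

    enzyme_or_transporter: str      # CYP3A4 | CYP3A7 | PGP | unspecific_hepatic
    Km: float | None = None
    kcat: float | None = None
    k: float | None = None
    product: str = "undefined"

    def __post_init__(self) -> None:
        if self.Km is not None and self.Km <= 0:
            raise ValueError("Km must be positive")
        for v in (self.kcat, self.k):
            if v is not None and v < 0:
                raise ValueError("rate constants must be >= 0")


@dataclass(frozen=True)
class InteractionParams:
    """Mechanism-based (irreversible) inactivation, optionally + competitive."""

    perpetrator: str
    target_enzyme: str = "CYP3A4"
    K_I: float = 9.33               # umol/L
    k_inact: float = 0.015          # 1/min
    Ki_competitive: float | None = None   # umol/L; None = irreversible only
    enzyme_turnover_kdeg: float = 0.0005  # 1/min (~36 h CYP3A4 half-life)

    def __post_init__(self) -> None:
        if self.K_I <= 0:
            raise ValueError("K_I must be positive")
        if self.k_inact < 0:
            raise ValueError("k_inact must be >= 0")


@dataclass(frozen=True)
class PartitionSet:
    """Organ -> cell:plasma partition coefficient."""

    kp: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, organ: str) -> float:
        return self.kp[organ]


def load_fentanyl() -> tuple[CompoundParams, list[ProcessKinetics]]:
    """Fentanyl parameter set of the final parent-metabolite model."""
    compound = CompoundParams(
        name="fentanyl", MW=336.5, pKa_base=8.99, logP=3.49, fu_adult=0.208,
        B2P=0.87, GFR_fraction=1.00, partition_method="rodgers_rowland",
        permeability_method="charge_dependent_schmitt",
    )
    processes = [
        ProcessKinetics("CYP3A4", Km=117.0, kcat=20.6, product="norfentanyl"),
        ProcessKinetics("CYP3A7", Km=596.0, kcat=5.22, product="norfentanyl"),
        ProcessKinetics("unspecific_hepatic", k=1.46, product="undefined"),
        ProcessKinetics("PGP", Km=5.72, kcat=1.71, product="fentanyl"),
    ]
    return compound, processes


def load_norfentanyl() -> tuple[CompoundParams, list[ProcessKinetics]]:
    """Norfentanyl parameter set; eliminated renally, no metabolic processes."""
    compound = CompoundParams(
        name="norfentanyl", MW=232.3, pKa_base=10.03, logP=2.00, fu_adult=0.819,
        B2P=1.26, GFR_fraction=4.30, partition_method="schmitt",
        permeability_method="fixed", permeability_fixed=1.80e-2,
    )
    return compound, []


def load_voriconazole_interaction(ki_competitive: float | None = None,
                                  kdeg: float = 0.0005) -> InteractionParams:
    """CYP3A4 mechanism-based inactivation by voriconazole."""
    return InteractionParams(perpetrator="voriconazole",
                             Ki_competitive=ki_competitive,
                             enzyme_turnover_kdeg=kdeg)


def compute_partition_set(compound: CompoundParams,
                          individual: Individual) -> PartitionSet:
    """Cell:plasma partition coefficient per perfused organ.

    Dispatches on ``compound.partition_method``; deterministic given compound
    and tissue composition. Kp (total cell : total plasma) = Kpu * fu.
    """
    fu = unbound_plasma_fraction(compound, individual)
    kps: dict[str, float] = {}
    ka_ap = None
    if compound.partition_method == "rodgers_rowland":
        ka_ap = _pt.acidic_phospholipid_ka(compound.pKa_base, compound.logP,
                                           compound.fu_adult, compound.B2P)
    elif compound.partition_method != "schmitt":
        raise ValueError(f"unsupported partition method {compound.partition_method!r}")
    for organ in individual.organs:
        if organ.composition is None:     # blood pools
            continue
        comp = organ.composition
        if compound.partition_method == "rodgers_rowland":
            kpu = _pt.rodgers_rowland_kpu(comp, compound.pKa_base, compound.logP,
                                          ka_ap, adipose=(organ.name == "fat"))
        else:
            kpu = _pt.schmitt_kpu(comp, compound.pKa_base, compound.logP)
        kp = kpu * fu
        if kp <= 0:
            raise ValueError(f"non-positive Kp for {organ.name}")
        kps[organ.name] = kp
    return PartitionSet(kp=kps)


def compute_permeability(compound: CompoundParams) -> float:
    """Permeability into the cellular space, cm/min."""
    return _pt.permeability_cm_min(compound.permeability_method, compound.MW,
                                   compound.logP, compound.pKa_base,
                                   fixed=compound.permeability_fixed)


def unbound_plasma_fraction(compound: CompoundParams,
                            individual: Individual) -> float:
    """fu in this individual's plasma: AAG-ratio scaling of the adult value."""
    return scale_fu(compound.fu_adult, individual.aag_ratio)


def compound_from_yaml(text: str) -> tuple[CompoundParams, list[ProcessKinetics]]:
    doc = yaml.safe_load(text)
    compound = CompoundParams(**doc["compound"])
    processes = [ProcessKinetics(**p) for p in doc.get("processes", [])]
    return compound, processes


def compound_to_yaml(compound: CompoundParams,
                     processes: list[ProcessKinetics]) -> str:
    def clean(d: dict) -> dict:
        return {k: v for k, v in d.items() if v is not None}
    doc = {
        "compound": clean(vars(compound).copy()),
        "processes": [clean(vars(p).copy()) for p in processes],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def with_kinetics(processes: list[ProcessKinetics], **overrides) -> list[ProcessKinetics]:
    """Return a copy of a process list with named constants replaced.

    Override keys: ``kcat_CYP3A4``, ``kcat_CYP3A7``, ``kcat_Pgp``, ``Km_Pgp``,
    ``unspecific_k``.
    """
    key_map = {
        "kcat_CYP3A4": ("CYP3A4", "kcat"), "kcat_CYP3A7": ("CYP3A7", "kcat"),
        "kcat_Pgp": ("PGP", "kcat"), "Km_Pgp": ("PGP", "Km"),
        "unspecific_k": ("unspecific_hepatic", "k"),
    }
    out = list(processes)
    for key, value in overrides.items():
        if key not in key_map:
            raise KeyError(f"unknown kinetic override {key!r}")
        target, attr = key_map[key]
        for i, p in enumerate(out):
            if p.enzyme_or_transporter == target:
                out[i] = replace(p, **{attr: value})
                break
        else:
            raise KeyError(f"no {target} process to override")
    return out
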