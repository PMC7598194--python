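"""Whole-body PBPK ODE engine for one or two coupled analytes.

Model structure
---------------
Every perfused organ is split into a vascular, an interstitial and a cellular
sub-compartment. Blood circulates venous pool -> lung -> arterial pool ->
systemic organs -> venous pool, with the gut organs draining through the
portal vein into the liver (which additionally receives a hepatic-artery
inflow). Drug exchanges vascular <-> interstitial at a perfusion-scaled
conductance and interstitial <-> cellular at a permeability-surface-area
conductance; all exchange fluxes are driven by unbound-concentration
differences, so tissue partitioning (Kp) and plasma/interstitial binding set
the equilibria.

Elimination processes (parent analyte):

* CYP3A4 and CYP3A7 saturable conversion to the metabolite in liver cells,
  rate = kcat * E(t) * [E]_ref * V_cell * Cu / (Km + Cu);
* first-order unspecific hepatic clearance acting on the amount in liver
  vascular plasma (an unbound-intracellular variant is available);
* P-gp saturable efflux from the cellular space of liver, gut, kidney
  (terminal, into an efflux accumulator) and brain (back into blood);
* renal filtration GFR_fraction * GFR * fu * C_plasma from kidney plasma.

The metabolite produced in liver cells enters its own whole-body distribution
system and is cleared renally. A CYP3A4 activity state E(t) implements
mechanism-based inactivation by a perpetrator concentration profile:
dE/dt = kdeg (E0 - E) - kinact I/(K_I + I) E, optionally combined with
competitive inhibition (Km multiplied by 1 + I/Ki).

Internal units: amounts in umol, time in minutes, volumes in L. Reported
concentrations are ng/mL; reported cumulative pathway amounts are ug.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import compound as _cmp
from .compound import CompoundParams, InteractionParams, PartitionSet, ProcessKinetics
from .physiology import Individual, PORTAL_ORGANS, build_individual, \
    enzyme_reference_concentrations
from .partition import CELL_SURFACE_PER_VOLUME

__all__ = [
    "DoseEvent", "PerpetratorProfile", "PBPKModel", "SimulationResult",
    "assemble_model", "default_model", "modified", "simulate",
    "pathway_fractions", "summary_pk", "EngineError",
]

PATHWAYS = ("CYP3A4", "CYP3A7", "unspecific_hepatic", "urine_parent",
            "urine_metabolite", "Pgp_efflux")

# Vascular <-> interstitial exchange conductance as a multiple of organ blood
# flow: large enough that the two spaces stay near equilibrium (the exchange is
# perfusion-limited), small enough to keep the system integrable.
KAPPA_VI = 20.0


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous administration (bolus if duration == 0)."""

    analyte: str
    time_start: float          # h
    duration: float            # h; 0 => bolus
    amount: float              # ug, or ug/kg when per_kg
    per_kg: bool = False
    route: str = "iv"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.route != "iv":
            raise ValueError("only the iv route is supported")


class PerpetratorProfile:
    """Unbound perpetrator liver concentration vs time (umol/L)."""

    def __init__(self, times_h: np.ndarray, conc_umol_l: np.ndarray):
        self.times_h = np.asarray(times_h, dtype=float)
        self.conc = np.asarray(conc_umol_l, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.conc.shape:
            raise ValueError("times and concentrations must be 1-D and aligned")

    @classmethod
    def constant(cls, conc_umol_l: float) -> "PerpetratorProfile":
        return cls(np.array([0.0, 1.0]), np.array([conc_umol_l, conc_umol_l]))

    def __call__(self, t_min: float) -> float:
        return float(np.interp(t_min / 60.0, self.times_h, self.conc))


@dataclass
class _MMTerm:
    """One Michaelis-Menten process in the assembled ODE system."""

    vmax: float                # umol/min at full enzyme activity
    km: float                  # umol/L
    cu_per_amount: float       # unbound conc per amount in the source state
    source: int
    targets: tuple[tuple[int, float], ...]   # (state index, stoichiometry)
    uses_enzyme_state: bool = False
    competitive: bool = False  # Km scaled by (1 + I/Ki)


@dataclass
class PBPKModel:
    """Assembled ODE system plus the assembly spec needed to rebuild it."""

    n: int
    L: np.ndarray                       # constant linear part (n x n), 1/min
    mm_terms: list[_MMTerm]
    dose_index: dict[str, int]          # analyte -> venous state index
    conc_map: dict[tuple[str, str], tuple[int, float]]   # (site, analyte) -> (idx, umol->ng/mL)
    amounts_map: dict[str, tuple[int, float]]            # pathway -> (idx, umol->ug)
    balance_indices: np.ndarray         # states + terminal sinks for mass balance
    state_names: list[str]
    body_weight: float
    parent: str
    metabolite_present: bool
    enzyme_index: int | None = None
    interaction: InteractionParams | None = None
    spec: dict = field(default_factory=dict)

    # -- one-compartment degenerate model (same integration path) -----------
    @classmethod
    def one_compartment(cls, volume_l: float, k_per_min: float,
                        mw: float = 336.5, name: str = "drug") -> "PBPKModel":
        """Single well-mixed compartment with first-order elimination.

        Shares the dosing/event/integration machinery of the full model, so it
        serves as an analytic oracle for the integrator.
        """
        L = np.array([[-k_per_min, 0.0], [k_per_min, 0.0]])
        return cls(
            n=2, L=L, mm_terms=[], dose_index={name: 0},
            conc_map={("venous_plasma", name): (0, mw / volume_l)},
            amounts_map={"unspecific_hepatic": (1, mw)},
            balance_indices=np.array([0, 1]),
            state_names=[f"{name}:central", "acc:eliminated"],
            body_weight=1.0, parent=name, metabolite_present=False,
        )


@dataclass
class SimulationResult:
    """Time grid, concentrations, cumulative pathway amounts, balance check."""

    time: np.ndarray                            # h
    conc: dict[tuple[str, str], np.ndarray]     # (site, analyte) -> ng/mL
    amounts: dict[str, np.ndarray]              # pathway -> cumulative ug
    dose_parent_ug: float
    mass_balance: np.ndarray                    # relative error series

    @property
    def mass_balance_error(self) -> float:
        return float(np.max(self.mass_balance)) if self.mass_balance.size else 0.0


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_model(individual: Individual,
                   analytes: list[tuple[CompoundParams, PartitionSet, list[ProcessKinetics]]],
                   interaction: InteractionParams | None = None,
                   expression_multipliers: dict[str, float] | None = None,
                   unspecific_on_plasma: bool = True) -> PBPKModel:
    """Assemble the whole-body ODE right-hand side for the given analytes.

    ``analytes`` lists the parent first; a metabolite (referenced as a process
    product of an earlier analyte) may follow. ``expression_multipliers``
    scale CYP3A4/CYP3A7/PGP expression and the unspecific clearance rate
    around the individual's ontogeny baseline (population variability).
    """
    mult = {"CYP3A4": 1.0, "CYP3A7": 1.0, "PGP": 1.0, "unspecific_hepatic": 1.0}
    if expression_multipliers:
        unknown = set(expression_multipliers) - set(mult)
        if unknown:
            raise ValueError(f"unknown expression multipliers: {sorted(unknown)}")
        mult.update(expression_multipliers)

    names = [c.name for c, _, _ in analytes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte names")
    for i, (c, _, procs) in enumerate(analytes):
        for p in procs:
            if p.product in names and names.index(p.product) < i:
                raise ValueError(
                    f"metabolite {p.product!r} listed before its parent {c.name!r}")

    perfused = [o for o in individual.organs if o.composition is not None]
    organ_names = [o.name for o in perfused]
    n_per = 3 * len(perfused) + 3          # + arterial, venous, portal states
    n = n_per * len(analytes) + 1 + len(PATHWAYS)   # + enzyme state + accumulators

    state_names: list[str] = []
    idx = {}
    for a, (c, _, _) in enumerate(analytes):
        off = a * n_per
        for i, o in enumerate(perfused):
            idx[(c.name, o.name, "vas")] = off + 3 * i
            idx[(c.name, o.name, "int")] = off + 3 * i + 1
            idx[(c.name, o.name, "cell")] = off + 3 * i + 2
            state_names += [f"{c.name}:{o.name}:{s}" for s in ("vas", "int", "cell")]
        idx[(c.name, "arterial")] = off + 3 * len(perfused)
        idx[(c.name, "venous")] = off + 3 * len(perfused) + 1
        idx[(c.name, "portal")] = off + 3 * len(perfused) + 2
        state_names += [f"{c.name}:{p}" for p in ("arterial", "venous", "portal")]
    e_idx = n_per * len(analytes)
    state_names.append("enzyme:CYP3A4")
    acc = {p: e_idx + 1 + i for i, p in enumerate(PATHWAYS)}
    state_names += [f"acc:{p}" for p in PATHWAYS]

    hct = individual.hematocrit
    co = individual.cardiac_output
    gfr_l_min = individual.GFR / 1000.0
    v_art = individual.organ("arterial_blood").total_volume
    v_ven = individual.organ("venous_blood").total_volume
    v_pv = individual.organ("portal_vein").total_volume
    q_pv = sum(individual.organ(o).blood_flow for o in PORTAL_ORGANS)
    q_ha = individual.organ("liver").blood_flow
    ref_conc = enzyme_reference_concentrations()

    L = np.zeros((n, n))
    mm_terms: list[_MMTerm] = []

    for a, (comp, kps, procs) in enumerate(analytes):
        fu = _cmp.unbound_plasma_fraction(comp, individual)
        b2p = comp.B2P
        perm = _cmp.compute_permeability(comp)
        i_art, i_ven, i_pv = (idx[(comp.name, k)] for k in
                              ("arterial", "venous", "portal"))

        # blood pool outflows
        L[i_ven, i_ven] -= co / v_ven                       # venous -> lung
        L[i_art, i_art] -= co / v_art                       # arterial -> organs
        L[i_pv, i_pv] -= q_pv / v_pv                        # portal -> liver

        for o in perfused:
            iv_, ii_, ic_ = (idx[(comp.name, o.name, s)] for s in ("vas", "int", "cell"))
            v_vas = o.total_volume * o.vascular_fraction
            v_int = o.total_volume * o.interstitial_fraction
            v_cell = o.total_volume * o.cellular_fraction
            q = o.blood_flow
            kp = kps[o.name]
            fu_int = 1.0 / (1.0 + (1.0 - fu) / fu * o.composition.albumin_ratio)

            # perfusion in/out
            if o.name == "lung":
                L[iv_, i_ven] += co / v_ven
                L[iv_, iv_] -= co / v_vas
                L[i_art, iv_] += co / v_vas
            elif o.name == "liver":
                L[iv_, i_art] += q_ha / v_art
                L[iv_, i_pv] += q_pv / v_pv
                L[iv_, iv_] -= (q_ha + q_pv) / v_vas
                L[i_ven, iv_] += (q_ha + q_pv) / v_vas
            elif o.name in PORTAL_ORGANS:
                L[iv_, i_art] += q / v_art
                L[iv_, iv_] -= q / v_vas
                L[i_pv, iv_] += q / v_vas
            else:
                L[iv_, i_art] += q / v_art
                L[iv_, iv_] -= q / v_vas
                L[i_ven, iv_] += q / v_vas

            # vascular <-> interstitial (unbound-gradient, perfusion-scaled)
            q_ex = co if o.name == "lung" else q_ha + q_pv if o.name == "liver" else q
            g = KAPPA_VI * q_ex
            cva = fu / (b2p * v_vas)          # unbound plasma conc per vascular amount
            cia = fu_int / v_int
            L[iv_, iv_] -= g * cva
            L[ii_, iv_] += g * cva
            L[iv_, ii_] += g * cia
            L[ii_, ii_] -= g * cia

            # interstitial <-> cellular (permeability-limited)
            ps = CELL_SURFACE_PER_VOLUME * perm * v_cell
            cca = fu / (kp * v_cell)          # unbound conc per cellular amount
            L[ii_, ii_] -= ps * cia
            L[ic_, ii_] += ps * cia
            L[ii_, ic_] += ps * cca
            L[ic_, ic_] -= ps * cca

            # renal filtration from kidney vascular plasma
            if o.name == "kidney" and comp.GFR_fraction > 0:
                c = comp.GFR_fraction * gfr_l_min * fu / (b2p * v_vas)
                L[iv_, iv_] -= c
                urine = acc["urine_parent"] if a == 0 else acc["urine_metabolite"]
                L[urine, iv_] += c

        # process kinetics
        liv = individual.organ("liver")
        v_liv_cell = liv.total_volume * liv.cellular_fraction
        v_liv_vas = liv.total_volume * liv.vascular_fraction
        kp_liv = kps["liver"]
        i_lv, i_lc = idx[(comp.name, "liver", "vas")], idx[(comp.name, "liver", "cell")]
        for p in procs:
            kind = p.enzyme_or_transporter
            if kind == "unspecific_hepatic":
                k_eff = p.k * mult["unspecific_hepatic"]
                if unspecific_on_plasma:
                    c = k_eff * (1.0 - hct) / b2p
                    L[i_lv, i_lv] -= c
                    L[acc["unspecific_hepatic"], i_lv] += c
                else:
                    c = k_eff * fu / kp_liv
                    L[i_lc, i_lc] -= c
                    L[acc["unspecific_hepatic"], i_lc] += c
            elif kind in ("CYP3A4", "CYP3A7"):
                e = (ref_conc[(kind, "liver")] * individual.enzyme_levels[kind]
                     * mult[kind])
                vmax = p.kcat * e * v_liv_cell
                targets = [(acc[kind], 1.0)]
                if p.product in names and names.index(p.product) != a:
                    targets.append((idx[(p.product, "liver", "cell")], 1.0))
                mm_terms.append(_MMTerm(
                    vmax=vmax, km=p.Km, cu_per_amount=fu / (kp_liv * v_liv_cell),
                    source=i_lc, targets=tuple(targets),
                    uses_enzyme_state=(kind == "CYP3A4"),
                    competitive=(kind == "CYP3A4"),
                ))
            elif kind == "PGP":
                for o in perfused:
                    if o.pgp_destination == "none" or (kind, o.name) not in ref_conc:
                        continue
                    v_cell = o.total_volume * o.cellular_fraction
                    e = (ref_conc[(kind, o.name)] * individual.enzyme_levels["PGP"]
                         * mult["PGP"])
                    if o.pgp_destination == "excreta":
                        target = (acc["Pgp_efflux"], 1.0)
                    else:
                        target = (idx[(comp.name, o.name, "vas")], 1.0)
                    mm_terms.append(_MMTerm(
                        vmax=p.kcat * e * v_cell, km=p.Km,
                        cu_per_amount=fu / (kps[o.name] * v_cell),
                        source=idx[(comp.name, o.name, "cell")],
                        targets=(target,),
                    ))
            else:
                raise ValueError(f"unknown process {kind!r}")

    metabolite_present = len(analytes) > 1
    sinks = [acc["unspecific_hepatic"], acc["urine_parent"],
             acc["urine_metabolite"], acc["Pgp_efflux"]]
    if not metabolite_present:
        sinks += [acc["CYP3A4"], acc["CYP3A7"]]   # conversion flux ends in a sink
    balance = np.array(list(range(n_per * len(analytes))) + sinks)

    parent_name = analytes[0][0].name
    conc_map = {}
    for comp, _, _ in analytes:
        conc_map[("venous_plasma", comp.name)] = (
            idx[(comp.name, "venous")], comp.MW / (v_ven * comp.B2P))
        conc_map[("arterial_plasma", comp.name)] = (
            idx[(comp.name, "arterial")], comp.MW / (v_art * comp.B2P))
    mw_parent = analytes[0][0].MW
    mw_met = analytes[1][0].MW if metabolite_present else mw_parent
    amounts_map = {p: (acc[p], mw_met if p == "urine_metabolite" else mw_parent)
                   for p in PATHWAYS}

    return PBPKModel(
        n=n, L=L, mm_terms=mm_terms,
        dose_index={c.name: idx[(c.name, "venous")] for c, _, _ in analytes},
        conc_map=conc_map, amounts_map=amounts_map, balance_indices=balance,
        state_names=state_names, body_weight=individual.body_weight,
        parent=parent_name, metabolite_present=metabolite_present,
        enzyme_index=e_idx, interaction=interaction,
        spec=dict(individual=individual, analytes=list(analytes),
                  interaction=interaction,
                  expression_multipliers=dict(mult),
                  unspecific_on_plasma=unspecific_on_plasma),
    )


def default_model(individual: Individual | None = None,
                  metabolite: bool = True,
                  interaction: InteractionParams | None = None,
                  expression_multipliers: dict[str, float] | None = None,
                  **kinetic_overrides) -> PBPKModel:
    """Fentanyl(+norfentanyl) model for an individual (adult reference default)."""
    if individual is None:
        individual = build_individual("male", 30.0)
    fen, fen_procs = _cmp.load_fentanyl()
    if kinetic_overrides:
        fen_procs = _cmp.with_kinetics(fen_procs, **kinetic_overrides)
    analytes = [(fen, _cmp.compute_partition_set(fen, individual), fen_procs)]
    if metabolite:
        nor, nor_procs = _cmp.load_norfentanyl()
        analytes.append((nor, _cmp.compute_partition_set(nor, individual), nor_procs))
    return assemble_model(individual, analytes, interaction=interaction,
                          expression_multipliers=expression_multipliers)


def modified(model: PBPKModel, **overrides) -> PBPKModel:
    """Rebuild a model with named parameter overrides.

    Supported: kinetic constants (``kcat_CYP3A4``, ``kcat_CYP3A7``,
    ``kcat_Pgp``, ``Km_Pgp``, ``unspecific_k``), ``GFR_fraction_<analyte>``,
    ``surgery_factor`` (multiplies both CYP kcats and the unspecific rate
    constant by 1 - factor), and ``expression_multipliers``.
    """
    if not model.spec:
        raise EngineError("model carries no assembly spec; cannot rebuild")
    spec = dict(model.spec)
    analytes = [list(a) for a in spec["analytes"]]
    kin = {k: v for k, v in overrides.items()
           if k in ("kcat_CYP3A4", "kcat_CYP3A7", "kcat_Pgp", "Km_Pgp",
                    "unspecific_k")}
    if "surgery_factor" in overrides:
        f = overrides["surgery_factor"]
        if not 0.0 <= f < 1.0:
            raise ValueError("surgery factor must be in [0, 1)")
        procs = {p.enzyme_or_transporter: p for p in analytes[0][2]}
        kin.setdefault("kcat_CYP3A4", procs["CYP3A4"].kcat)
        kin.setdefault("kcat_CYP3A7", procs["CYP3A7"].kcat)
        kin.setdefault("unspecific_k", procs["unspecific_hepatic"].k)
        kin = {k: v * (1.0 - f) if k in ("kcat_CYP3A4", "kcat_CYP3A7",
                                         "unspecific_k") else v
               for k, v in kin.items()}
    if kin:
        analytes[0][2] = _cmp.with_kinetics(analytes[0][2], **kin)
    for i, (comp, kps, procs) in enumerate(analytes):
        key = f"GFR_fraction_{comp.name}"
        if key in overrides:
            analytes[i][0] = replace(comp, GFR_fraction=overrides[key])
    mults = dict(spec["expression_multipliers"])
    mults.update(overrides.get("expression_multipliers", {}))
    return assemble_model(spec["individual"], [tuple(a) for a in analytes],
                          interaction=spec["interaction"],
                          expression_multipliers=mults,
                          unspecific_on_plasma=spec["unspecific_on_plasma"])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _default_grid(seg_starts: list[float], t_end: float) -> np.ndarray:
    """Dense right after events, geometric later in each segment (minutes)."""
    pieces = [np.array([0.0])]
    bounds = sorted(set(seg_starts + [t_end]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = b - a
        fine = a + np.arange(0.25, min(seg, 10.0), 0.25)
        mid = a + np.arange(10.0, min(seg, 120.0), 1.0)
        parts = [fine, mid]
        if seg > 120.0:
            parts.append(a + np.geomspace(120.0, seg, 160))
        parts.append(np.array([b]))
        pieces.extend(parts)
    grid = np.unique(np.concatenate(pieces))
    return grid[(grid >= 0) & (grid <= t_end + 1e-9)]


def simulate(model: PBPKModel,
             regimen: list[DoseEvent],
             t_end: float,
             perpetrator_profile: PerpetratorProfile | None = None,
             t_eval_h: np.ndarray | None = None,
             rtol: float = 1e-9,
             atol: float = 1e-12,
             method: str = "BDF") -> SimulationResult:
    """Integrate the model over ``[0, t_end]`` hours under a dosing regimen."""
    if model.interaction is not None and perpetrator_profile is None:
        raise EngineError("model has an interaction configured; a perpetrator "
                          "concentration profile is required")
    if model.interaction is None and perpetrator_profile is not None:
        raise EngineError("perpetrator profile supplied but the model has no "
                          "interaction configured")
    t_end_min = t_end * 60.0
    for ev in regimen:
        if ev.analyte not in model.dose_index:
            raise EngineError(f"unknown analyte {ev.analyte!r} in regimen")
        if (ev.time_start + ev.duration) * 60.0 > t_end_min + 1e-9:
            raise EngineError("t_end must cover the last dose event")

    boluses: dict[float, list[tuple[int, float]]] = {}
    windows = []   # (start_min, end_min, state index, rate umol/min)
    event_times = {0.0, t_end_min}
    total_dose_umol = 0.0
    mw_by_analyte = {comp.name: comp.MW
                     for comp, *_ in model.spec.get("analytes", [])}
    mw_parent = mw_by_analyte.get(model.parent,
                                  model.amounts_map["unspecific_hepatic"][1])
    for ev in regimen:
        ug = ev.amount * (model.body_weight if ev.per_kg else 1.0)
        umol = ug / mw_by_analyte.get(ev.analyte, mw_parent)
        t0 = ev.time_start * 60.0
        if ev.duration == 0:
            boluses.setdefault(t0, []).append((model.dose_index[ev.analyte], umol))
            event_times.add(t0)
        else:
            t1 = t0 + ev.duration * 60.0
            windows.append((t0, t1, model.dose_index[ev.analyte],
                            umol / (ev.duration * 60.0)))
            event_times.update((t0, t1))
        total_dose_umol += umol

    if t_eval_h is None:
        grid = _default_grid(sorted(event_times - {t_end_min}), t_end_min)
    else:
        grid = np.asarray(t_eval_h, dtype=float) * 60.0

    L = model.L
    mm = model.mm_terms
    inter = model.interaction
    e_idx = model.enzyme_index
    kdeg = inter.enzyme_turnover_kdeg if inter else 0.0
    kinact = inter.k_inact if inter else 0.0
    k_i = inter.K_I if inter else 1.0
    ki_comp = inter.Ki_competitive if inter else None

    def inhibitor(t: float) -> float:
        return perpetrator_profile(t) if perpetrator_profile is not None else 0.0

    def rhs_factory(u: np.ndarray):
        def rhs(t, y):
            dy = L @ y + u
            ii = inhibitor(t) if inter else 0.0
            for term in mm:
                cu = term.cu_per_amount * y[term.source]
                km = term.km
                if term.competitive and ki_comp:
                    km = km * (1.0 + ii / ki_comp)
                act = y[e_idx] if term.uses_enzyme_state else 1.0
                v = term.vmax * act * cu / (km + cu)
                dy[term.source] -= v
                for tgt, stoich in term.targets:
                    dy[tgt] += stoich * v
            if inter:
                dy[e_idx] = kdeg * (1.0 - y[e_idx]) - kinact * ii / (k_i + ii) * y[e_idx]
            return dy

        def jac(t, y):
            J = L.copy()
            ii = inhibitor(t) if inter else 0.0
            for term in mm:
                cu = term.cu_per_amount * y[term.source]
                km = term.km
                if term.competitive and ki_comp:
                    km = km * (1.0 + ii / ki_comp)
                act = y[e_idx] if term.uses_enzyme_state else 1.0
                dv_ds = term.vmax * act * km * term.cu_per_amount / (km + cu) ** 2
                J[term.source, term.source] -= dv_ds
                for tgt, stoich in term.targets:
                    J[tgt, term.source] += stoich * dv_ds
                if term.uses_enzyme_state:
                    dv_de = term.vmax * cu / (km + cu)
                    J[term.source, e_idx] -= dv_de
                    for tgt, stoich in term.targets:
                        J[tgt, e_idx] += stoich * dv_de
            if inter:
                J[e_idx, :] = 0.0
                J[e_idx, e_idx] = -kdeg - kinact * ii / (k_i + ii)
            return J

        return rhs, jac

    y = np.zeros(model.n)
    if e_idx is not None:
        y[e_idx] = 1.0
    bounds = sorted(event_times)
    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    dosed: list[np.ndarray] = []
    dosed_so_far = 0.0

    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        for si, umol in boluses.get(t0, []):
            y[si] += umol
            dosed_so_far += umol
        u = np.zeros(model.n)
        seg_rate = 0.0
        for w0, w1, si, rate in windows:
            if w0 <= t0 + 1e-12 and t1 <= w1 + 1e-12:
                u[si] += rate
                seg_rate += rate
        mask = (grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)
        t_seg = np.unique(np.clip(grid[mask], t0, t1))
        rhs, jac = rhs_factory(u)
        sol = solve_ivp(rhs, (t0, t1), y, method=method, jac=jac,
                        rtol=rtol, atol=atol,
                        t_eval=t_seg if t_seg.size else np.array([t1]),
                        first_step=min(1e-3, (t1 - t0) / 10))
        if not sol.success:
            raise EngineError(f"integrator failed at t = {sol.t[-1]/60.0:.4g} h: "
                              f"{sol.message}")
        if t_seg.size:
            t_out.append(sol.t)
            y_out.append(sol.y.T)
            dosed.append(dosed_so_far + seg_rate * (sol.t - t0))
        # advance the true state to the segment end
        if abs(sol.t[-1] - t1) > 1e-9:
            sol2 = solve_ivp(rhs, (sol.t[-1] if sol.t.size else t0, t1),
                             sol.y[:, -1] if sol.t.size else y,
                             method=method, jac=jac, rtol=rtol, atol=atol)
            if not sol2.success:
                raise EngineError(f"integrator failed at t = {sol2.t[-1]/60.0:.4g} h")
            y = sol2.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()
        dosed_so_far += seg_rate * (t1 - t0)

    t_min = np.concatenate(t_out) if t_out else np.array([0.0])
    Y = np.vstack(y_out) if y_out else np.zeros((1, model.n))
    dosed_arr = np.concatenate(dosed) if dosed else np.array([0.0])
    keep = np.concatenate(([True], np.diff(t_min) > 1e-12))
    t_min, Y, dosed_arr = t_min[keep], Y[keep], dosed_arr[keep]

    floor = max(1e-9 * max(total_dose_umol, 1.0), 100 * atol)
    state_min = Y[:, :model.balance_indices.max() + 1].min()
    if state_min < -floor:
        raise EngineError(f"negative state beyond tolerance: {state_min:.3g} umol")

    conc = {key: np.maximum(Y[:, i], 0.0) * f
            for key, (i, f) in model.conc_map.items()}
    amounts = {p: np.maximum(Y[:, i], 0.0) * mw
               for p, (i, mw) in model.amounts_map.items()}
    if total_dose_umol > 0:
        balance = np.abs(Y[:, model.balance_indices].sum(axis=1) - dosed_arr) \
            / total_dose_umol
    else:
        balance = np.zeros_like(t_min)

    return SimulationResult(
        time=t_min / 60.0, conc=conc, amounts=amounts,
        dose_parent_ug=total_dose_umol * mw_parent, mass_balance=balance,
    )


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def pathway_fractions(result: SimulationResult,
                      min_eliminated: float = 0.99) -> dict[str, float]:
    """Fraction of eliminated parent dose per elimination pathway.

    Requires the simulation to have run until at least ``min_eliminated`` of
    the dose is eliminated; fractions are normalized over the eliminated
    amount and sum to 1.
    """
    parent_pathways = ("CYP3A4", "CYP3A7", "unspecific_hepatic",
                       "urine_parent", "Pgp_efflux")
    elim = {p: result.amounts[p][-1] for p in parent_pathways}
    total = sum(elim.values())
    if result.dose_parent_ug > 0 and total < min_eliminated * result.dose_parent_ug:
        raise EngineError(
            f"only {total/result.dose_parent_ug:.1%} of the dose eliminated; "
            "extend t_end to reach >= 99% before computing pathway fractions")
    if total <= 0:
        raise EngineError("nothing eliminated")
    return {p: v / total for p, v in elim.items()}


def summary_pk(result: SimulationResult, site: str, analyte: str) -> dict[str, float]:
    """AUC_last (linear trapezoid), Cmax and Tmax for one series."""
    key = (site, analyte)
    if key not in result.conc:
        raise KeyError(f"no series for {key}")
    c = result.conc[key]
    if c.size == 0:
        raise ValueError("empty series")
    auc = float(np.trapezoid(c, result.time))
    imax = int(np.argmax(c))
    return {"AUC_last": auc, "Cmax": float(c[imax]), "Tmax": float(result.time[imax])}
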