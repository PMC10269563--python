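"""Five-phase dFBA integrator with direct FBA coupling.

Batch fermentation is split into lag, exponential growth, nitrogen-limited
growth, stationary and decay phases with estimated boundaries T_L < T_E <
T_S < T_D.  Each phase has its own cellular objective:

* lag — maximize ATPase expenditure,
* exponential — maximize growth,
* nitrogen-limited — maximize growth with a carbohydrate-enriched biomass,
* stationary/decay — maximize ATP production and protein synthesis
  jointly (weights normalized by each flux's standalone optimum).

At every step of an adaptive ODE integration the phase's FBA problem is
solved under the kinetic exchange bounds, parsimonious FBA resolves
degeneracy, and the extracellular state advances as dC/dt = v_ex * DW,
dDW/dt = mu * DW.  The integrator restarts at phase boundaries because
objectives and constraints switch discontinuously there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cobra.util.array import create_stoichiometric_matrix
from scipy.integrate import solve_ivp

from . import biomass as bm
from . import kinetics as kin
from .lp import FbaProblem, FluxSolution, INF
from .network import open_excretion

logger = logging.getLogger(__name__)

PHASES = kin.PHASES


class DfbaError(RuntimeError):
    """Integration failure carrying time, phase and constraint context."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase boundaries in hours: lag ends at T_L, exponential at T_E,
    N-limited growth at T_S, stationary at T_D; decay runs to t_end."""

    T_L: float
    T_E: float
    T_S: float
    T_D: float
    t_end: float

    def __post_init__(self):
        if not (0.0 < self.T_L < self.T_E < self.T_S < self.T_D
                <= self.t_end):
            raise ValueError(
                f"phase times must satisfy 0 < T_L < T_E < T_S < T_D <= "
                f"t_end, got {self}")

    @property
    def boundaries(self):
        return (self.T_L, self.T_E, self.T_S, self.T_D)

    def segments(self):
        edges = (0.0,) + self.boundaries + (self.t_end,)
        return [(PHASES[i], edges[i], edges[i + 1]) for i in range(5)
                if edges[i + 1] > edges[i]]


def phase_of(t: float, schedule: PhaseSchedule) -> str:
    """Half-open phase assignment: [0,T_L) lag ... [T_D, t_end] decay."""
    if t < 0 or t > schedule.t_end:
        raise ValueError(f"t={t} outside [0, {schedule.t_end}]")
    for phase, edge in zip(PHASES[:4], schedule.boundaries):
        if t < edge:
            return phase
    return "decay"


@dataclass
class SolverOptions:
    """Integration and LP options.

    fast=True trades accuracy for speed during parameter estimation:
    looser tolerances, no pFBA stage inside the right-hand side, LP solves
    only in the growth phases (all exchange fluxes are kinetically forced
    in lag/stationary/decay, with zero nitrogen uptake, matching the
    parsimonious LP solution there), and no flux recording.
    """

    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9
    pfba: bool = True
    fast: bool = False
    record_fluxes: bool = True
    max_step: float = INF

    @classmethod
    def fast_preset(cls):
        return cls(method="RK23", rtol=1e-4, atol=1e-7, pfba=False,
                   fast=True, record_fluxes=False)


@dataclass
class Trajectory:
    """Time-stamped extracellular state, biomass and fluxes."""

    times: np.ndarray
    states: np.ndarray              # n_times x n_state
    state_names: list
    phases: list
    schedule: PhaseSchedule
    fluxes: np.ndarray | None = None   # n_times x n_reactions
    reaction_ids: list | None = None
    sv_residual: np.ndarray | None = None  # max |S v| per step, S as solved

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def flux(self, reaction_id: str) -> np.ndarray:
        if self.fluxes is None:
            raise ValueError("trajectory recorded without fluxes")
        return self.fluxes[:, self.reaction_ids.index(reaction_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "time_h", self.times)
        df.insert(1, "phase", self.phases)
        return df

    def flux_frame(self) -> pd.DataFrame:
        if self.fluxes is None:
            raise ValueError("trajectory recorded without fluxes")
        df = pd.DataFrame(self.fluxes, columns=self.reaction_ids)
        df.insert(0, "time_h", self.times)
        return df


def build_objective(phase: str, atpm_value=1.0):
    """Objective description for a phase: reaction-id weight map, or the
    marker 'atp_protein' for the normalized two-flux combination."""
    if phase == "lag":
        return {"ATPM": 1.0}
    if phase == "exponential":
        return {"BIOMASS": 1.0}
    if phase == "n_limited":
        return {"BIOMASS_CARB": 1.0}
    if phase in ("stationary", "decay"):
        return "atp_protein"
    raise ValueError(f"unknown phase {phase}")


class DfbaProblem:
    """Compiled dFBA problem over a cobra model plus kinetics/schedule."""

    #: reactions whose fluxes enter the stationary multi-objective
    ATP_RXN = "ATPM"
    PROT_RXN = "PROTSYN"

    def __init__(self, model, params: kin.KineticParameters,
                 schedule: PhaseSchedule, initial_state: dict,
                 species_exchanges: dict, protein_curve: bm.ProteinCurve,
                 nitrogen_atoms: dict, lipid_excretion=("mev_c",),
                 rho=0.05, dna_fraction=0.01, lipid_fraction=0.05,
                 precursors: bm.PrecursorMap | None = None):
        model = open_excretion(model, lipid_excretion)
        self.model = model
        self.params = params
        self.schedule = schedule
        self.protein_curve = protein_curve
        self.nitrogen_atoms = nitrogen_atoms
        self.rho = rho
        self.dna_fraction = dna_fraction
        self.lipid_fraction = lipid_fraction
        self.precursors = precursors or bm.PrecursorMap.default()

        self.reaction_ids = [r.id for r in model.reactions]
        self.rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        self.S = create_stoichiometric_matrix(model)
        self.lb0 = np.array([r.lower_bound for r in model.reactions])
        self.ub0 = np.array([r.upper_bound for r in model.reactions])

        # state layout: DW first, then species
        self.aa_names = list(params.k_AA)
        self.product_names = list(params.k_P)
        self.state_names = (["DW", "glucose", "fructose", "ammonium"]
                            + self.aa_names + ["arginine", "oxygen"]
                            + self.product_names)
        missing = [s for s in self.state_names[1:]
                   if s not in species_exchanges]
        if missing:
            raise KeyError(f"no exchange mapping for species: {missing}")
        self.species_exchanges = species_exchanges
        self.ex_idx = {s: self.rxn_index[species_exchanges[s]]
                       for s in self.state_names[1:]}
        self.y0 = np.array([initial_state["DW"]] +
                           [initial_state.get(s, 0.0)
                            for s in self.state_names[1:]])

        # lipid-excretion exchanges: open in stationary/decay only
        self._lipid_ex = []
        for sid in lipid_excretion:
            met = model.metabolites.get_by_id(sid)
            self._lipid_ex += [self.rxn_index[r.id] for r in met.reactions
                               if r.boundary]

        self._prob = FbaProblem(self.S, self.lb0, self.ub0)
        self._phase_bounds = {p: self._make_phase_bounds(p) for p in PHASES}
        self._objectives = {p: build_objective(p) for p in PHASES}
        self._last_protein = None
        self._biomass_cols = {
            rid: self.rxn_index[rid]
            for rid in ("BIOMASS", "BIOMASS_CARB")
            if rid in self.rxn_index}
        self._n_lp = 0

    # -- factory -----------------------------------------------------------
    @classmethod
    def from_preset(cls, preset, model=None):
        from . import toy
        model = model or toy.build_toy_model()
        return cls(model, preset.params.copy(), preset.schedule,
                   preset.initial_state, toy.SPECIES_EXCHANGES,
                   preset.protein_curve, toy.NITROGEN_ATOMS,
                   lipid_excretion=preset.lipid_excretion,
                   rho=preset.rho, dna_fraction=preset.dna_fraction,
                   lipid_fraction=preset.lipid_fraction)

    # -- bounds and objectives --------------------------------------------
    def _make_phase_bounds(self, phase):
        lb = self.lb0.copy()
        ub = self.ub0.copy()
        for rid, j in (("BIOMASS", None), ("BIOMASS_CARB", None)):
            if rid not in self.rxn_index:
                continue
            j = self.rxn_index[rid]
            active = (phase == "exponential" and rid == "BIOMASS") or \
                     (phase == "n_limited" and rid == "BIOMASS_CARB")
            lb[j], ub[j] = (0.0, 1000.0) if active else (0.0, 0.0)
        for j in self._lipid_ex:
            if phase in ("stationary", "decay"):
                lb[j], ub[j] = 0.0, 1000.0
            else:
                lb[j], ub[j] = 0.0, 0.0
        return lb, ub

    def _state_dict(self, y):
        return {name: max(float(v), 0.0)
                for name, v in zip(self.state_names, y)}

    def _kinetic_bounds(self, phase, st):
        """(lb, ub) arrays for the phase under the current state."""
        lb, ub = (a.copy() for a in self._phase_bounds[phase])
        p = self.params
        v_glx, v_f = kin.hexose_uptake_bounds(st["glucose"], st["fructose"],
                                              st.get("ethanol", 0.0), p)
        self._set_eq(lb, ub, "glucose", v_glx)
        self._set_eq(lb, ub, "fructose", v_f)
        self._set_eq(lb, ub, "oxygen", kin.oxygen_bound(st["oxygen"], p))
        nh4_lb, aa_lb, arg_lb = kin.nitrogen_uptake_bounds(
            st["ammonium"], {a: st[a] for a in self.aa_names},
            st["arginine"], p, phase)
        self._set_range(lb, ub, "ammonium", nh4_lb, 0.0)
        for a in self.aa_names:
            self._set_range(lb, ub, a, aa_lb[a], 0.0)
        self._set_range(lb, ub, "arginine", arg_lb, 0.0)
        prods = kin.product_constraints(v_glx, v_f, p)
        for name in self.product_names:
            if name == "acetate" and phase in ("stationary", "decay"):
                self._set_eq(lb, ub, name,
                             kin.acetate_uptake_bound(st["acetate"], p))
            else:
                self._set_eq(lb, ub, name, prods[name])
        return lb, ub

    def _set_eq(self, lb, ub, species, value):
        j = self.ex_idx[species]
        lb[j] = ub[j] = value

    def _set_range(self, lb, ub, species, lo, hi):
        j = self.ex_idx[species]
        lb[j], ub[j] = lo, hi

    def _update_biomass(self, st):
        """Refresh the dynamic biomass columns from the current YAN."""
        yan = bm.yan_of_state(st, self.nitrogen_atoms)
        protein = self.protein_curve(yan)
        key = (round(protein, 5), self.params.gam_f)
        if self._last_protein == key:
            return
        self._last_protein = key
        comp = bm.compose_biomass(protein, self.dna_fraction,
                                  self.lipid_fraction, self.rho)
        for rid, j in self._biomass_cols.items():
            c = comp if rid == "BIOMASS" else bm.carb_shifted(comp,
                                                              rho=self.rho)
            gam = bm.total_gam(c, self.params.gam_f)
            stoich = bm.biomass_stoichiometry(c, gam, self.precursors)
            rows = [self.met_index[m] for m in stoich]
            vals = list(stoich.values())
            self._prob.set_column(j, rows, vals)

    def _objective_vector(self, phase, lb, ub, pfba):
        n = len(self.reaction_ids)
        spec = self._objectives[phase]
        if spec == "atp_protein":
            weights = {}
            for rid in (self.ATP_RXN, self.PROT_RXN):
                c = np.zeros(n)
                c[self.rxn_index[rid]] = 1.0
                self._prob.set_bounds(lb, ub, pfba=False)
                sol = self._prob.solve(c, pfba=False)
                self._n_lp += 1
                z = sol.objective_value if sol.status == "optimal" else 0.0
                weights[rid] = 1.0 / z if z > 1e-9 else 0.0
            c = np.zeros(n)
            for rid, w in weights.items():
                c[self.rxn_index[rid]] = w
            return c
        c = np.zeros(n)
        for rid, w in spec.items():
            c[self.rxn_index[rid]] = w
        return c

    # -- core solves -------------------------------------------------------
    def solve_phase(self, phase, y, pfba=True) -> FluxSolution:
        """Solve the phase FBA/pFBA at a given raw state vector."""
        st = self._state_dict(y)
        lb, ub = self._kinetic_bounds(phase, st)
        if phase in ("exponential", "n_limited"):
            self._update_biomass(st)
        c = self._objective_vector(phase, lb, ub, pfba)
        self._prob.set_bounds(lb, ub, pfba=pfba)
        sol = self._prob.solve(c, pfba=pfba)
        self._n_lp += 1
        if sol.status != "optimal":
            raise DfbaError(
                f"FBA {sol.status} at t-state in phase {phase}: "
                f"{sol.message}")
        return sol

    def _forced_exchange_fluxes(self, phase, st):
        """Exchange fluxes in phases where kinetics fully determine them
        (used by fast mode).  Nitrogen uptake is zero in these phases:
        with growth disabled the parsimonious solution takes none — the
        stationary ATP+protein objective is exactly indifferent between
        burning ATP and paying the polymerization cost, and the pFBA
        stage then drops the longer protein route."""
        p = self.params
        v = {}
        v_glx, v_f = kin.hexose_uptake_bounds(st["glucose"], st["fructose"],
                                              st.get("ethanol", 0.0), p)
        v["glucose"], v["fructose"] = v_glx, v_f
        v["oxygen"] = kin.oxygen_bound(st["oxygen"], p)
        v["ammonium"] = 0.0
        for a in self.aa_names:
            v[a] = 0.0
        v["arginine"] = 0.0
        prods = kin.product_constraints(v_glx, v_f, p)
        for name in self.product_names:
            if name == "acetate" and phase in ("stationary", "decay"):
                v[name] = kin.acetate_uptake_bound(st["acetate"], p)
            else:
                v[name] = prods[name]
        return v

    def rhs(self, t, y, phase, options: SolverOptions):
        """Time-derivatives of [DW, concentrations] in the given phase."""
        dw = max(float(y[0]), 0.0)
        st = self._state_dict(y)
        dy = np.zeros_like(y)
        if options.fast and phase not in ("exponential", "n_limited"):
            vex = self._forced_exchange_fluxes(phase, st)
            for i, name in enumerate(self.state_names[1:], start=1):
                dy[i] = vex[name] * dw
            mu = 0.0
        else:
            try:
                sol = self.solve_phase(phase, y, pfba=options.pfba)
            except DfbaError as exc:
                raise DfbaError(f"t={t:.3f} h, phase={phase}: {exc}") from exc
            for i, name in enumerate(self.state_names[1:], start=1):
                dy[i] = sol.v[self.ex_idx[name]] * dw
            mu = 0.0
            if phase == "exponential":
                mu = sol.v[self.rxn_index["BIOMASS"]]
            elif phase == "n_limited":
                mu = sol.v[self.rxn_index["BIOMASS_CARB"]]
        if phase == "decay":
            dy[0] = -self.params.k_d * dw
        else:
            dy[0] = mu * dw
        return dy

    # -- integration -------------------------------------------------------
    def simulate(self, options: SolverOptions | None = None) -> Trajectory:
        options = options or SolverOptions()
        y = self.y0.copy()
        times, states, phases = [], [], []
        for phase, t0, t1 in self.schedule.segments():
            self._last_protein = None  # force biomass refresh per phase
            sol = solve_ivp(self.rhs, (t0, t1), y, method=options.method,
                            rtol=options.rtol, atol=options.atol,
                            max_step=options.max_step,
                            args=(phase, options))
            if not sol.success:
                raise DfbaError(
                    f"integration failed in phase {phase}: {sol.message}; "
                    f"state={dict(zip(self.state_names, y))}")
            start = 1 if times and sol.t[0] == times[-1][-1] else 0
            times.append(sol.t[start:])
            states.append(np.clip(sol.y[:, start:].T, 0.0, None))
            phases += [phase] * (len(sol.t) - start)
            y = np.clip(sol.y[:, -1], 0.0, None)
        t_all = np.concatenate(times)
        y_all = np.vstack(states)
        fluxes = resid = None
        if options.record_fluxes:
            fluxes = np.empty((len(t_all), len(self.reaction_ids)))
            resid = np.empty(len(t_all))
            for k, (tk, yk, ph) in enumerate(zip(t_all, y_all, phases)):
                fluxes[k] = self.solve_phase(ph, yk, pfba=True).v
                # residual against the stoichiometry in effect at this step
                # (the dynamic biomass column changes along the trajectory)
                resid[k] = np.abs(self._prob.S @ fluxes[k]).max()
        return Trajectory(times=t_all, states=y_all,
                          state_names=self.state_names, phases=phases,
                          schedule=self.schedule, fluxes=fluxes,
                          reaction_ids=list(self.reaction_ids)
                          if options.record_fluxes else None,
                          sv_residual=resid)


def solve_fba(model, objective: dict, bounds: dict | None = None,
              pfba: bool = True) -> FluxSolution:
    """One-shot (p)FBA on a cobra model with optional bound overrides.

    objective: reaction-id -> weight.  bounds: reaction-id -> (lb, ub).
    """
    S = create_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    for rid, (lo, hi) in (bounds or {}).items():
        if lo > hi:
            raise ValueError(f"bounds inconsistent for {rid}: {lo} > {hi}")
        lb[idx[rid]], ub[idx[rid]] = lo, hi
    c = np.zeros(len(lb))
    for rid, w in objective.items():
        c[idx[rid]] = w
    return FbaProblem(S, lb, ub).solve(c, pfba=pfba)
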