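"""Least-squares parameter estimation against fermentation time series.

The objective is the squared distance between model predictions and
observations, with each variable normalized by the mean of its own
readouts:

    J(theta) = sum_j sum_i ((y_ji(theta) - y^m_ji) / q_j)^2,  q_j = mean_j

Predictions are interpolated from the simulated trajectory (monotone
cubic) to the sampling times.  The search is a seeded, bounded global
optimizer (differential evolution) over a user-chosen parameter subset;
fits are reproducible given the seed and never leave the declared box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import differential_evolution

from .engine import DfbaError, DfbaProblem, PhaseSchedule, SolverOptions

logger = logging.getLogger(__name__)

PENALTY_SIM_FAILURE = 1e8
PENALTY_BAD_SCHEDULE = 1e6

SCHEDULE_FIELDS = ("T_L", "T_E", "T_S", "T_D", "t_end")
CURVE_FIELDS = ("p_min", "p_max", "k_p")


@dataclass
class MeasurementSet:
    """Observed time series in internal units (mM; DW in gDW/L).

    data: long-format frame with columns variable, time_h, value.
    Weights q are per-variable scalars: the mean observed readout.
    """

    data: pd.DataFrame
    t_end: float | None = None

    def __post_init__(self):
        need = {"variable", "time_h", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"measurements need columns {sorted(need)}")
        if len(self.data) == 0:
            raise ValueError("no records in measurement set")
        if self.t_end is not None:
            bad = self.data[(self.data.time_h < 0) |
                            (self.data.time_h > self.t_end)]
            if len(bad):
                raise ValueError("sampling times outside [0, t_end]")
        self.weights = self.data.groupby("variable")["value"].mean().to_dict()
        zero_q = [v for v, q in self.weights.items() if q <= 0]
        if zero_q:
            raise ValueError(f"nonpositive normalization weight for {zero_q}")

    @property
    def variables(self):
        return sorted(self.weights)

    def observations(self, variable):
        sub = self.data[self.data.variable == variable]
        return sub["time_h"].to_numpy(), sub["value"].to_numpy()


def r_squared(predictions: dict, observations: dict) -> dict:
    """Per-variable R^2 = 1 - SS_res/SS_tot; None if zero variance."""
    out = {}
    for var, obs in observations.items():
        obs = np.asarray(obs, dtype=float)
        pred = np.asarray(predictions[var], dtype=float)
        if len(obs) < 2:
            raise ValueError(f"need >= 2 observations for {var}")
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        if ss_tot == 0:
            out[var] = None
            continue
        out[var] = 1.0 - np.sum((pred - obs) ** 2) / ss_tot
    return out


def apply_theta(problem: DfbaProblem, names, values):
    """Write a parameter vector into a DfbaProblem in place.

    Names address KineticParameters fields, dict entries ("k_P.ethanol",
    "k_AA.aa1"), schedule fields (T_L..t_end) and protein-curve fields
    (p_min, p_max, k_p).  Raises ValueError for an inconsistent phase
    ordering.
    """
    sched = {f: getattr(problem.schedule, f) for f in SCHEDULE_FIELDS}
    curve = {f: getattr(problem.protein_curve, f) for f in CURVE_FIELDS}
    sched_touched = curve_touched = False
    for name, value in zip(names, values):
        value = float(value)
        if name in SCHEDULE_FIELDS:
            sched[name] = value
            sched_touched = True
        elif name in CURVE_FIELDS:
            curve[name] = value
            curve_touched = True
        elif "." in name:
            group, key = name.split(".", 1)
            getattr(problem.params, group)[key] = value
        else:
            if not hasattr(problem.params, name):
                raise KeyError(f"unknown parameter {name}")
            setattr(problem.params, name, value)
    if sched_touched:
        problem.schedule = PhaseSchedule(**sched)
    if curve_touched:
        from .biomass import ProteinCurve
        problem.protein_curve = ProteinCurve(**curve)


def schedule_violation(names, values, base: PhaseSchedule) -> float:
    """Total ordering violation (h) a candidate schedule would incur."""
    sched = {f: getattr(base, f) for f in SCHEDULE_FIELDS}
    for n, v in zip(names, values):
        if n in SCHEDULE_FIELDS:
            sched[n] = float(v)
    seq = [0.0] + [sched[f] for f in SCHEDULE_FIELDS]
    return sum(max(0.0, a - b) for a, b in zip(seq[:-1], seq[1:]))


def lsq_objective(problem: DfbaProblem, measurements: MeasurementSet,
                  options: SolverOptions | None = None) -> float:
    """J at the problem's current parameters (simulation + interpolation).

    Simulation failure returns a large finite penalty so global search
    can continue.
    """
    options = options or SolverOptions.fast_preset()
    try:
        traj = problem.simulate(options)
    except DfbaError as exc:
        logger.warning("simulation failed during estimation: %s", exc)
        return PENALTY_SIM_FAILURE
    J = 0.0
    for var in measurements.variables:
        if var not in problem.state_names:
            raise KeyError(f"measured variable {var} is not simulated")
        t_obs, y_obs = measurements.observations(var)
        interp = PchipInterpolator(traj.times, traj.state(var),
                                   extrapolate=True)
        pred = interp(np.clip(t_obs, traj.times[0], traj.times[-1]))
        q = measurements.weights[var]
        J += float(np.sum(((pred - y_obs) / q) ** 2))
    return J


@dataclass
class FitResult:
    """Outcome of a global fit."""

    theta: dict
    J: float
    r2: dict
    seed: int
    n_evaluations: int
    bounds: dict
    trace: list = field(default_factory=list)

    def to_dict(self):
        return {"theta": self.theta, "J": self.J, "r2": self.r2,
                "seed": self.seed, "n_evaluations": self.n_evaluations,
                "bounds": {k: list(v) for k, v in self.bounds.items()},
                "trace": self.trace}


def fit(problem: DfbaProblem, measurements: MeasurementSet, bounds: dict,
        seed: int, budget: int = 5000,
        options: SolverOptions | None = None, popsize: int = 15) -> FitResult:
    """Global bounded fit of the named parameters.

    bounds: parameter-name -> (lower, upper).  budget caps objective
    evaluations.  Deterministic given the seed; the returned J is never
    worse than the best point of the initial population.
    """
    options = options or SolverOptions.fast_preset()
    names = list(bounds)
    box = [tuple(map(float, bounds[n])) for n in names]
    base_schedule = problem.schedule
    count = [0]
    best = [np.inf, None]
    trace = []

    def objective(x):
        count[0] += 1
        viol = schedule_violation(names, x, base_schedule)
        if viol > 0:
            return PENALTY_BAD_SCHEDULE * (1.0 + viol)
        try:
            apply_theta(problem, names, x)
        except (ValueError, KeyError) as exc:
            logger.debug("rejected theta %s: %s", x, exc)
            return PENALTY_BAD_SCHEDULE
        J = lsq_objective(problem, measurements, options)
        if J < best[0]:
            best[0], best[1] = J, np.array(x)
            trace.append((count[0], float(J)))
        return J

    ndim = len(names)
    rng = np.random.default_rng(seed)
    if budget < 2 * popsize * ndim:
        # degenerate budget: best of a space-filling sample
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        n_samp = max(1, budget)
        samples = lo + (hi - lo) * rng.random((n_samp, ndim))
        for x in samples:
            objective(x)
    else:
        maxiter = max(1, budget // (popsize * ndim) - 2)
        differential_evolution(objective, box, seed=seed, popsize=popsize,
                               maxiter=maxiter, tol=1e-8, polish=False,
                               init="latinhypercube", updating="immediate")
    if best[1] is None:
        raise DfbaError("all evaluated parameter vectors were infeasible")
    apply_theta(problem, names, best[1])
    r2 = fit_r_squared(problem, measurements, options)
    return FitResult(theta=dict(zip(names, map(float, best[1]))),
                     J=float(best[0]), r2=r2, seed=seed,
                     n_evaluations=count[0],
                     bounds=dict(zip(names, box)), trace=trace)


def fit_r_squared(problem: DfbaProblem, measurements: MeasurementSet,
                  options: SolverOptions | None = None) -> dict:
    """R^2 per measured variable at the problem's current parameters."""
    options = options or SolverOptions.fast_preset()
    traj = problem.simulate(options)
    preds, obs = {}, {}
    for var in measurements.variables:
        t_obs, y_obs = measurements.observations(var)
        interp = PchipInterpolator(traj.times, traj.state(var),
                                   extrapolate=True)
        preds[var] = interp(np.clip(t_obs, traj.times[0], traj.times[-1]))
        obs[var] = y_obs
    return r_squared(preds, obs)
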