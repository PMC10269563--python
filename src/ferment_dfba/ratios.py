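"""Dynamic flux-ratio analysis.

For each reaction i and fermentation phase window, accumulate the flux
weighted by biomass and normalize by the accumulated hexose consumption:

    S_i = 100 * int v_i(t) DW(t) dt / H,   H = |int (v_Glx + v_F) DW dt|

in mmol of compound per mmol of hexose consumed x 100.  The denominator
is the accumulated hexose consumption as a positive quantity, so
production ratios are positive and uptake ratios negative (the glucose
and fructose exchange entries themselves sum to -100 by construction).
Windows: growth [T_L, T_S], stationary [T_S, T_D], decay [T_D, t_end]
(a whole-run option integrates 0..t_end instead of the decay window).
Integrals use the trapezoidal rule on the accepted integration steps.
Tables from two conditions are compared as log2 fold changes of |S| and
filtered by magnitude and fold thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Trajectory

logger = logging.getLogger(__name__)

PHASE_WINDOWS = ("growth", "stationary", "decay")


def phase_window(phase: str, schedule, whole_run: bool = False):
    if phase == "growth":
        return schedule.T_L, schedule.T_S
    if phase == "stationary":
        return schedule.T_S, schedule.T_D
    if phase == "decay":
        if whole_run:
            return 0.0, schedule.t_end
        return schedule.T_D, schedule.t_end
    raise ValueError(f"unknown ratio phase {phase} (use {PHASE_WINDOWS})")


def _accumulate(traj: Trajectory, values: np.ndarray, t0: float, t1: float):
    """Trapezoidal integral of values(t)*DW(t) over [t0, t1]."""
    mask = (traj.times >= t0 - 1e-12) & (traj.times <= t1 + 1e-12)
    if mask.sum() < 2:
        raise ValueError(f"trajectory does not cover [{t0}, {t1}]")
    t = traj.times[mask]
    integrand = values[mask] * traj.state("DW")[mask]
    return np.trapezoid(integrand, t)


def hexose_integral(traj: Trajectory, glucose_ex: str, fructose_ex: str,
                    t0: float, t1: float) -> float:
    return (_accumulate(traj, traj.flux(glucose_ex), t0, t1) +
            _accumulate(traj, traj.flux(fructose_ex), t0, t1))


def phase_flux_ratio(traj: Trajectory, reaction: str, phase: str,
                     glucose_ex: str = "EX_glc_e",
                     fructose_ex: str = "EX_fru_e",
                     whole_run: bool = False) -> float:
    """S_{i,phase} for one reaction; NaN when no hexose was consumed."""
    t0, t1 = phase_window(phase, traj.schedule, whole_run)
    hex_cons = -hexose_integral(traj, glucose_ex, fructose_ex, t0, t1)
    if hex_cons == 0.0:
        logger.warning("zero hexose integral in %s window; ratio undefined",
                       phase)
        return np.nan
    num = _accumulate(traj, traj.flux(reaction), t0, t1)
    return 100.0 * num / hex_cons


def flux_ratio_table(traj: Trajectory, reactions=None,
                     glucose_ex: str = "EX_glc_e",
                     fructose_ex: str = "EX_fru_e",
                     whole_run: bool = False) -> pd.DataFrame:
    """S_{i,phase} for all (or selected) reactions x the three windows."""
    if traj.fluxes is None:
        raise ValueError("trajectory was recorded without fluxes")
    reactions = list(reactions) if reactions is not None \
        else list(traj.reaction_ids)
    cols = {}
    dw = traj.state("DW")
    for phase in PHASE_WINDOWS:
        t0, t1 = phase_window(phase, traj.schedule, whole_run)
        mask = (traj.times >= t0 - 1e-12) & (traj.times <= t1 + 1e-12)
        t = traj.times[mask]
        w = dw[mask]
        hex_cons = -(np.trapezoid(traj.flux(glucose_ex)[mask] * w, t) +
                     np.trapezoid(traj.flux(fructose_ex)[mask] * w, t))
        idx = [traj.reaction_ids.index(r) for r in reactions]
        integ = np.trapezoid(traj.fluxes[mask][:, idx] * w[:, None],
                             t, axis=0)
        cols[phase] = (100.0 * integ / hex_cons if hex_cons != 0.0
                       else np.full(len(idx), np.nan))
    return pd.DataFrame(cols, index=pd.Index(reactions, name="reaction"))


def log2_fold(s_a: float, s_b: float) -> float:
    """log2(|S_a| / |S_b|); raises on zero or sign-inconsistent input."""
    if s_a == 0 or s_b == 0:
        raise ValueError("zero flux ratio has no fold change")
    if np.sign(s_a) != np.sign(s_b):
        raise ValueError(f"sign change between {s_a} and {s_b}; "
                         "fold change not comparable")
    return float(np.log2(abs(s_a) / abs(s_b)))


def select_differential(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        phase: str = "stationary",
                        mag_threshold: float = 0.1,
                        fold_threshold: float = 1.0) -> pd.DataFrame:
    """Reactions with max(|S_a|,|S_b|) > mag and |log2 fold| > threshold.

    Sign-inconsistent pairs are excluded and flagged in the 'sign_change'
    column of the returned frame (sorted by |fold| descending).
    """
    shared = table_a.index.intersection(table_b.index)
    rows = []
    for rid in shared:
        sa, sb = table_a.loc[rid, phase], table_b.loc[rid, phase]
        if np.isnan(sa) or np.isnan(sb):
            continue
        if max(abs(sa), abs(sb)) <= mag_threshold:
            continue
        if sa == 0 or sb == 0 or np.sign(sa) != np.sign(sb):
            if abs(sa) > mag_threshold or abs(sb) > mag_threshold:
                rows.append((rid, sa, sb, np.nan, True))
            continue
        fold = log2_fold(sa, sb)
        if abs(fold) > fold_threshold:
            rows.append((rid, sa, sb, fold, False))
    out = pd.DataFrame(rows, columns=["reaction", "S_a", "S_b",
                                      "log2_fold", "sign_change"])
    out = out.reindex(out["log2_fold"].abs().sort_values(
        ascending=False, na_position="last").index)
    return out.set_index("reaction")
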