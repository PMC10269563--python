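"""Kinetic bounds coupling extracellular concentrations to the FBA problem.

Hexose transport follows Michaelis–Menten kinetics with noncompetitive
ethanol inhibition and is imposed as an equality; so are the proportional
product-formation constraints and the first-order oxygen flux.  Nitrogen
sources get one-sided lower bounds (the LP may take less): Michaelis–
Menten for ammonium, mass action for amino acids, with the arginine gate
closing from the stationary phase onward.  All concentrations are mM, all
fluxes mmol/(gDW h); uptake fluxes are negative by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

PHASES = ("lag", "exponential", "n_limited", "stationary", "decay")
GROWTH_PHASES = ("lag", "exponential", "n_limited")


@dataclass
class KineticParameters:
    """The estimable kinetic parameter vector (excluding phase times)."""

    vmax_G: float       # hexose uptake Vmax, mmol/(gDW h)
    k_G: float          # glucose half-saturation, mM
    vmax_F: float
    k_F: float
    K_Ei: float         # ethanol noncompetitive-inhibition constant, mM
    vmax_NH4: float
    k_NH4: float
    k_AA: dict          # amino-acid first-order constants, L/(gDW h)
    k_Arg: float
    k_O2: float
    k_P: dict           # product yields, mmol product / mmol hexose
    X_A: float = 1.0    # activity coefficient on product formation
    k_acetate_uptake: float = 0.0   # stationary first-order acetate uptake
    k_d: float = 0.0    # decay-phase first-order biomass decline, 1/h
    gam_f: float = 0.0  # residual GAM, mmol ATP/gDW

    def __post_init__(self):
        for name in ("vmax_G", "k_G", "vmax_F", "k_F", "K_Ei", "vmax_NH4",
                     "k_NH4", "k_Arg", "k_O2", "k_acetate_uptake", "k_d",
                     "gam_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.X_A <= 1.0:
            raise ValueError("X_A must lie in [0, 1]")

    def copy(self):
        return replace(self, k_AA=dict(self.k_AA), k_P=dict(self.k_P))


def _mm(conc, vmax, k):
    conc = max(conc, 0.0)
    if conc == 0.0:
        return 0.0
    if k == 0.0:
        logger.debug("zero half-saturation with substrate present; "
                     "treating as Vmax")
        return vmax
    return vmax * conc / (conc + k)


def hexose_uptake_bounds(glucose: float, fructose: float, ethanol: float,
                         params: KineticParameters):
    """Equality-constrained hexose fluxes (v_Glx, v_F), both <= 0."""
    inhibition = 1.0 / (1.0 + max(ethanol, 0.0) / params.K_Ei)
    v_glx = -_mm(glucose, params.vmax_G, params.k_G) * inhibition
    v_f = -_mm(fructose, params.vmax_F, params.k_F) * inhibition
    return v_glx, v_f


def nitrogen_uptake_bounds(nh4: float, amino_acids: dict, arginine: float,
                           params: KineticParameters, phase: str):
    """Lower bounds for the NH4, amino-acid and arginine exchanges.

    Returns (nh4_lb, {aa: lb}, arg_lb); the arginine bound is exactly 0
    from the stationary phase onward.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase}")
    nh4_lb = -_mm(nh4, params.vmax_NH4, params.k_NH4)
    aa_lb = {name: -params.k_AA[name] * max(conc, 0.0)
             for name, conc in amino_acids.items()}
    if phase in ("stationary", "decay"):
        arg_lb = 0.0
    else:
        arg_lb = -params.k_Arg * max(arginine, 0.0)
    return nh4_lb, aa_lb, arg_lb


def product_constraints(v_glx: float, v_f: float,
                        params: KineticParameters) -> dict:
    """Equality fluxes for each product: -X_A * k_P * (v_Glx + v_F) >= 0."""
    total = v_glx + v_f
    return {name: -params.X_A * k * total for name, k in params.k_P.items()}


def oxygen_bound(o2: float, params: KineticParameters) -> float:
    """First-order dissolved-oxygen flux, <= 0."""
    return -params.k_O2 * max(o2, 0.0)


def acetate_uptake_bound(acetate: float, params: KineticParameters) -> float:
    """Stationary/decay first-order acetate uptake (equality, <= 0)."""
    return -params.k_acetate_uptake * max(acetate, 0.0)
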