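"""Stoichiometric model handling: SBML I/O, curation edits, path yields.

Models are plain :class:`cobra.Model` objects throughout the package.  The
operations here cover the reconstruction edits this modelling framework
needs before simulation — removing reactions absent from a strain,
grafting the putative erythritol branch onto the pentose phosphate
pathway, and opening excretion routes for the stationary phase — plus a
closed-system LP query that measures the stoichiometric yield of a
product on a substrate (used to verify pathway claims such as the
acetyl-CoA and NADPH cost of mevalonate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix

from .lp import FbaProblem

logger = logging.getLogger(__name__)

LARGE_BOUND = 1000.0  # mmol/(gDW h), constraint-based modelling convention


class ModelError(ValueError):
    pass


def load_sbml(path) -> cobra.Model:
    """Read an SBML L3/FBC model; fail loudly on degenerate input."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml errors name the offending element
        raise ModelError(f"malformed SBML in {path}: {exc}") from exc
    if len(model.reactions) == 0:
        raise ModelError(f"no reactions in SBML file {path}")
    unbounded = [r.id for r in model.reactions
                 if r.lower_bound is None or r.upper_bound is None]
    if unbounded:
        raise ModelError(f"reactions without FBC bounds: {unbounded}")
    return model


def save_sbml(model: cobra.Model, path) -> None:
    cobra.io.write_sbml_model(model, str(path))


def remove_reactions(model: cobra.Model, ids) -> cobra.Model:
    """Return a copy of *model* lacking exactly the named reactions.

    Unknown ids abort the whole operation (no partial removal).  Orphaned
    metabolites are retained so the stoichiometric row indexing stays
    stable across curation steps; they are only logged.
    """
    ids = list(dict.fromkeys(ids))  # dedupe, keep order
    known = {r.id for r in model.reactions}
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise KeyError(f"unknown reaction ids: {unknown}")
    out = model.copy()
    if not ids:
        return out
    before = {m.id for m in out.metabolites if len(m.reactions) > 0}
    out.remove_reactions([out.reactions.get_by_id(i) for i in ids],
                         remove_orphans=False)
    orphaned = sorted(m for m in before
                      if len(out.metabolites.get_by_id(m).reactions) == 0)
    if orphaned:
        logger.info("metabolites orphaned by removal (retained): %s", orphaned)
    return out


_ERY_PREREQ = {
    "e4p": "erythrose-4-phosphate",
    "pi": "phosphate",
    "nadph": "NADPH",
    "nadp": "NADP+",
    "h": "H+",
}


def _find_cytosolic(model, stem):
    """Find metabolite `<stem>_c` or any cytosolic id starting with stem."""
    mid = f"{stem}_c"
    if mid in model.metabolites:
        return model.metabolites.get_by_id(mid)
    return None


def add_erythritol_pathway(model: cobra.Model) -> cobra.Model:
    """Add ery1, ery2 and an erythritol export to a copy of *model*.

    ery1: erythrose-4-phosphate -> erythrose + phosphate
    ery2: erythrose + NADPH + H+ -> erythritol + NADP+
    EX_erythritol_e: erythritol export to the extracellular medium

    Idempotent: a model that already carries the pathway is returned
    unchanged (with a warning).
    """
    out = model.copy()
    if "ery2" in out.reactions:
        warnings.warn("erythritol pathway already present; no-op")
        return out
    for stem, name in _ERY_PREREQ.items():
        if _find_cytosolic(out, stem) is None:
            raise ModelError(f"missing metabolite {name} ({stem}_c)")
    e4p = out.metabolites.get_by_id("e4p_c")
    pi = out.metabolites.get_by_id("pi_c")
    nadph = out.metabolites.get_by_id("nadph_c")
    nadp = out.metabolites.get_by_id("nadp_c")
    h = out.metabolites.get_by_id("h_c")
    h2o = _find_cytosolic(out, "h2o")
    erytro = cobra.Metabolite("erytro_c", name="erythrose", compartment="c",
                              formula="C4H8O4")
    eryol = cobra.Metabolite("eryol_c", name="erythritol", compartment="c",
                             formula="C4H10O4")
    r1 = cobra.Reaction("ery1", name="erythrose-4-phosphate phosphatase",
                        lower_bound=0.0, upper_bound=LARGE_BOUND)
    stoich1 = {e4p: -1.0, erytro: 1.0, pi: 1.0}
    if h2o is not None:
        stoich1[h2o] = -1.0
    r1.add_metabolites(stoich1)
    r2 = cobra.Reaction("ery2", name="erythrose reductase (NADPH)",
                        lower_bound=0.0, upper_bound=LARGE_BOUND)
    r2.add_metabolites({erytro: -1.0, nadph: -1.0, h: -1.0,
                        eryol: 1.0, nadp: 1.0})
    r3 = cobra.Reaction("EX_erythritol_e", name="erythritol export",
                        lower_bound=0.0, upper_bound=LARGE_BOUND)
    r3.add_metabolites({eryol: -1.0})
    out.add_reactions([r1, r2, r3])
    return out


def open_excretion(model: cobra.Model, species_ids) -> cobra.Model:
    """Open (or create) export-only exchanges for the given species.

    Export unbounded at the conventional large bound, import closed.
    Already-open exchanges are left untouched (idempotent).
    """
    out = model.copy()
    for sid in species_ids:
        if sid not in out.metabolites:
            raise KeyError(f"unknown species {sid}")
        met = out.metabolites.get_by_id(sid)
        exch = [r for r in met.reactions if r.boundary]
        if exch:
            rxn = exch[0]
            if rxn.upper_bound < LARGE_BOUND:
                rxn.upper_bound = LARGE_BOUND
            if rxn.lower_bound < 0.0:
                rxn.lower_bound = 0.0
        else:
            stem = sid.rsplit("_", 1)[0]
            rxn = cobra.Reaction(f"EX_{stem}_e", name=f"{stem} export",
                                 lower_bound=0.0, upper_bound=LARGE_BOUND)
            rxn.add_metabolites({met: -1.0})
            out.add_reactions([rxn])
    return out


# default cofactor pairs opened as free interconversions in yield queries;
# (from, to) meaning a pseudo-reaction `to -> from` whose flux measures net
# consumption of `from` by the pathway under study
DEFAULT_FREE_PAIRS = (("atp_c", "adp_c"), ("atp_c", "amp_c"),
                      ("nadh_c", "nad_c"), ("nadph_c", "nadp_c"))
DEFAULT_OPEN_SINKS = ("h2o_c", "h_c", "pi_c", "co2_c", "nh4_c", "o2_c",
                      "ppi_c")


@dataclass
class PathwayYield:
    """Result of a closed-system substrate-to-product yield query."""

    yield_per_substrate: float        # mmol product per mmol substrate
    substrate_per_product: float      # inverse, when yield > 0
    cofactor_per_product: float | None  # net tracked-cofactor consumption
    status: str
    diagnostic: str = ""


def pathway_yield(model: cobra.Model, substrate: str, product: str,
                  tracked_cofactor: str | None = None,
                  free_pairs=DEFAULT_FREE_PAIRS,
                  open_sinks=DEFAULT_OPEN_SINKS) -> PathwayYield:
    """Maximum product yield per unit substrate under S.v = 0.

    All exchanges are closed except a unit substrate uptake, the product
    export and the declared inorganic sinks.  Cofactor pairs are made
    freely interconvertible through regeneration pseudo-reactions; at the
    pFBA optimum the flux through the tracked pair's regeneration reaction
    equals the pathway's net consumption of that cofactor (negative for
    net production).
    """
    if substrate == product:
        return PathwayYield(1.0, 1.0, 0.0, "optimal", "identity path")
    work = model.copy()
    # close every boundary reaction
    for rxn in work.reactions:
        if rxn.boundary:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    regen_ids = {}
    for red, ox in free_pairs:
        if red not in work.metabolites or ox not in work.metabolites:
            continue
        rid = f"REGEN_{red}_{ox}"
        r = cobra.Reaction(rid, name=f"free {ox}->{red} regeneration",
                           lower_bound=-LARGE_BOUND, upper_bound=LARGE_BOUND)
        r.add_metabolites({work.metabolites.get_by_id(ox): -1.0,
                           work.metabolites.get_by_id(red): 1.0})
        work.add_reactions([r])
        regen_ids.setdefault(red, rid)
    for sid in open_sinks:
        if sid in work.metabolites:
            met = work.metabolites.get_by_id(sid)
            exch = [r for r in met.reactions if r.boundary]
            if exch:
                exch[0].lower_bound = -LARGE_BOUND
                exch[0].upper_bound = LARGE_BOUND

    def _exchange_for(sid):
        met = work.metabolites.get_by_id(sid)
        exch = [r for r in met.reactions if r.boundary]
        if exch:
            return exch[0]
        # give the queried species a temporary boundary route
        r = cobra.Reaction(f"EX_query_{sid}", lower_bound=0.0,
                           upper_bound=0.0)
        r.add_metabolites({met: -1.0})
        work.add_reactions([r])
        return r

    sub_ex = _exchange_for(substrate)
    prod_ex = _exchange_for(product)
    sub_ex.lower_bound = -1.0
    sub_ex.upper_bound = -1.0
    prod_ex.lower_bound = 0.0
    prod_ex.upper_bound = LARGE_BOUND

    S = create_stoichiometric_matrix(work)
    lb = np.array([r.lower_bound for r in work.reactions])
    ub = np.array([r.upper_bound for r in work.reactions])
    rindex = {r.id: j for j, r in enumerate(work.reactions)}
    prob = FbaProblem(S, lb, ub)
    c = np.zeros(len(work.reactions))
    c[rindex[prod_ex.id]] = 1.0
    sol = prob.solve(c, pfba=True)
    if sol.status == "unbounded":
        raise ModelError(f"unbounded yield {substrate}->{product}: "
                         "the model leaks mass")
    if sol.status != "optimal":
        return PathwayYield(0.0, np.inf, None, sol.status,
                            f"no feasible route {substrate}->{product}: "
                            f"{sol.message}")
    y = sol.v[rindex[prod_ex.id]]
    if y <= 1e-10:
        return PathwayYield(0.0, np.inf, None, "optimal",
                            f"no route from {substrate} to {product}")
    cof = None
    if tracked_cofactor is not None:
        rid = regen_ids.get(tracked_cofactor)
        if rid is None:
            raise ModelError(
                f"tracked cofactor {tracked_cofactor} has no free pair")
        cof = sol.v[rindex[rid]] / y
    return PathwayYield(float(y), float(1.0 / y), cof, "optimal")


def check_mass_balance(model: cobra.Model, elements=("C", "N"),
                       strict=True, skip_prefixes=("EX_", "SK_", "REGEN_",
                                                   "DM_", "BIOMASS")):
    """Check elemental balance for the given elements.

    Returns a dict reaction-id -> {element: imbalance} for unbalanced
    reactions.  With strict=False, models lacking formulas only warn.
    """
    bad = {}
    for rxn in model.reactions:
        if rxn.boundary or any(rxn.id.startswith(p) for p in skip_prefixes):
            continue
        totals = dict.fromkeys(elements, 0.0)
        missing = False
        for met, coef in rxn.metabolites.items():
            if not met.formula:
                missing = True
                break
            comp = met.elements
            for el in elements:
                totals[el] += coef * comp.get(el, 0)
        if missing:
            if strict:
                bad[rxn.id] = {"missing_formula": True}
            continue
        imbal = {el: t for el, t in totals.items() if abs(t) > 1e-9}
        if imbal:
            bad[rxn.id] = imbal
    if bad and not strict:
        warnings.warn(f"element imbalance (advisory): {sorted(bad)}")
        return {}
    return bad


def model_summary(model: cobra.Model) -> dict:
    """JSON-ready summary: counts, compartments, bound extremes."""
    lbs = [r.lower_bound for r in model.reactions]
    ubs = [r.upper_bound for r in model.reactions]
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_exchanges": sum(1 for r in model.reactions if r.boundary),
        "compartments": sorted(set(m.compartment for m in model.metabolites)),
        "min_lower_bound": min(lbs) if lbs else None,
        "max_upper_bound": max(ubs) if ubs else None,
    }
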