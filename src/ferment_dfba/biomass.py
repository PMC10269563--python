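"""Dynamic biomass composition and growth-associated maintenance (GAM).

The biomass pseudoreaction lists the millimoles of monomeric precursors
needed to form 1 gDW of cells.  Its protein fraction follows the yeast
assimilable nitrogen (YAN) still available in the medium through a
saturating curve; mRNA is proportional to protein; DNA and lipid are
fixed; carbohydrates absorb the remaining mass.  GAM — the ATP hydrolysed
per gram of biomass formed — decomposes into polymerization costs per
polymer class plus a fitted species-dependent residual GAM_F, and is
carried by the ATP/ADP/phosphate coefficients of the pseudoreaction.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_MOLAR_MASS = 14.007  # g N / mol


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinCurve:
    """Saturating protein-vs-YAN curve: p_min + (p_max-p_min)*yan/(yan+k_p).

    p_min, p_max are mass fractions (g protein / gDW); k_p is the
    half-saturation YAN in mg N/L.
    """

    p_min: float
    p_max: float
    k_p: float

    def __post_init__(self):
        if self.p_min > self.p_max:
            raise CompositionError(
                f"p_min {self.p_min} exceeds p_max {self.p_max}")
        if self.k_p <= 0:
            raise CompositionError("k_p must be positive")

    def __call__(self, yan: float) -> float:
        yan = max(float(yan), 0.0)
        return self.p_min + (self.p_max - self.p_min) * yan / (yan + self.k_p)

    @classmethod
    def calibrated(cls, p_min: float, k_p: float, yan0: float,
                   p0: float) -> "ProteinCurve":
        """Solve p_max so the curve passes through (yan0, p0)."""
        if yan0 <= 0:
            raise CompositionError("yan0 must be positive for calibration")
        p_max = p_min + (p0 - p_min) * (yan0 + k_p) / yan0
        return cls(p_min, p_max, k_p)


def protein_fraction_of_yan(yan: float, params: ProteinCurve) -> float:
    return params(yan)


@dataclass(frozen=True)
class BiomassComposition:
    """Mass fractions of the five polymer classes; they sum to 1."""

    protein: float
    rna: float
    carb: float
    dna: float
    lipid: float

    def __post_init__(self):
        fr = self.as_dict()
        for name, f in fr.items():
            if not 0.0 <= f <= 1.0:
                raise CompositionError(f"{name} fraction {f} outside [0,1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise CompositionError(
                f"fractions sum to {sum(fr.values())}, not 1")

    def as_dict(self):
        return {"protein": self.protein, "rna": self.rna, "carb": self.carb,
                "dna": self.dna, "lipid": self.lipid}


def compose_biomass(protein_fraction: float, dna_fraction: float = 0.01,
                    lipid_fraction: float = 0.05,
                    rho: float = 0.05) -> BiomassComposition:
    """Build a composition from the protein fraction.

    rna = rho * protein (mRNA proportional to protein); carbohydrates
    absorb all remaining mass.
    """
    rna = rho * protein_fraction
    carb = 1.0 - protein_fraction - rna - dna_fraction - lipid_fraction
    if carb < -1e-12:
        raise CompositionError(
            f"protein fraction {protein_fraction} leaves negative "
            f"carbohydrate remainder {carb}")
    return BiomassComposition(protein=protein_fraction, rna=rna,
                              carb=max(carb, 0.0), dna=dna_fraction,
                              lipid=lipid_fraction)


def carb_shifted(comp: BiomassComposition, delta: float = 0.2,
                 rho: float = 0.05) -> BiomassComposition:
    """Carbohydrate-enriched variant: carb up by *delta* mass fraction,
    protein (and proportional RNA) down to compensate."""
    protein = comp.protein - delta / (1.0 + rho)
    if protein < 0:
        raise CompositionError("carbohydrate shift exceeds protein fraction")
    return compose_biomass(protein, dna_fraction=comp.dna,
                           lipid_fraction=comp.lipid, rho=rho)


@dataclass(frozen=True)
class GamBreakdown:
    """GAM decomposition, all in mmol ATP per gDW of biomass formed."""

    gam_f: float
    gam_prot: float
    gam_rna: float
    gam_carb: float
    gam_dna: float

    @property
    def total(self) -> float:
        return (self.gam_f + self.gam_prot + self.gam_rna + self.gam_carb +
                self.gam_dna)


def _data_path(name):
    return importlib.resources.files("ferment_dfba").joinpath("data").joinpath(name)


@functools.lru_cache(maxsize=1)
def _polymer_costs_cached() -> tuple:
    df = pd.read_csv(_data_path("polymer_costs.csv"))
    return tuple(zip(df["polymer"], df["mmol_atp_per_g"]))


def default_polymer_costs() -> dict:
    """Polymerization costs (mmol ATP per g polymer) shipped as data."""
    return dict(_polymer_costs_cached())


def total_gam(comp: BiomassComposition, gam_f: float,
              unit_costs: dict | None = None) -> GamBreakdown:
    if gam_f < 0:
        raise ValueError("gam_f must be nonnegative")
    costs = unit_costs or default_polymer_costs()
    return GamBreakdown(
        gam_f=gam_f,
        gam_prot=comp.protein * costs["protein"],
        gam_rna=comp.rna * costs["rna"],
        gam_carb=comp.carb * costs["carb"],
        gam_dna=comp.dna * costs["dna"],
    )


@dataclass
class PrecursorMap:
    """Maps each polymer class to monomer metabolites with molar masses.

    table columns: polymer, metabolite_id, molar_mass_g_per_mmol, weight.
    weight is the mass share of the polymer supplied by that monomer
    (weights within a polymer sum to 1).
    """

    table: pd.DataFrame

    def __post_init__(self):
        # plain-tuple view of the table for the per-step hot path
        self._rows = [(r["polymer"], r["metabolite_id"],
                       float(r["molar_mass_g_per_mmol"]), float(r["weight"]))
                      for _, r in self.table.iterrows()]

    @classmethod
    def default(cls) -> "PrecursorMap":
        return cls(pd.read_csv(_data_path("precursors.csv")))

    def monomer_coefficients(self, comp: BiomassComposition) -> dict:
        """mmol of each monomer consumed per gDW of biomass."""
        fractions = comp.as_dict()
        coeffs: dict[str, float] = {}
        for polymer, met, mass, weight in self._rows:
            mmol = fractions[polymer] * weight / mass
            coeffs[met] = coeffs.get(met, 0.0) + mmol
        return coeffs


def biomass_stoichiometry(comp: BiomassComposition, gam: GamBreakdown,
                          precursors: PrecursorMap) -> dict:
    """Full biomass pseudoreaction stoichiometry (metabolite id -> coeff,
    negative = consumed) for 1 gDW of biomass per unit flux."""
    stoich = {m: -c for m, c in precursors.monomer_coefficients(comp).items()}
    g = gam.total
    for met, coef in (("atp_c", -g), ("h2o_c", -g), ("adp_c", g),
                      ("pi_c", g), ("h_c", g)):
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich


def update_biomass_reaction(model, comp: BiomassComposition,
                            gam: GamBreakdown,
                            precursors: PrecursorMap | None = None,
                            reaction_id: str | None = None):
    """Rewrite the biomass pseudoreaction of a cobra model in place.

    Monomer coefficients are scaled so the consumed monomer mass totals
    1 g per unit flux; ATP/ADP/phosphate/H2O carry gam.total.
    """
    precursors = precursors or PrecursorMap.default()
    rid = reaction_id or getattr(model, "biomass_reaction_id", None) \
        or "BIOMASS"
    rxn = model.reactions.get_by_id(rid)
    stoich = biomass_stoichiometry(comp, gam, precursors)
    missing = [m for m in stoich if m not in model.metabolites]
    if missing:
        raise KeyError(f"biomass precursors absent from model: {missing}")
    rxn.subtract_metabolites(rxn.metabolites)  # clear
    rxn.add_metabolites({model.metabolites.get_by_id(m): c
                         for m, c in stoich.items()})
    return model


def monomer_mass_per_flux(comp: BiomassComposition,
                          precursors: PrecursorMap) -> float:
    """Total monomer grams consumed per unit biomass flux (mass closure)."""
    coeffs = precursors.monomer_coefficients(comp)
    masses = dict(zip(precursors.table["metabolite_id"],
                      precursors.table["molar_mass_g_per_mmol"]))
    return sum(c * masses[m] for m, c in coeffs.items())


def yan_of_state(concentrations: dict, nitrogen_atoms: dict) -> float:
    """YAN in mg N/L from mM concentrations and per-species N counts."""
    return N_MOLAR_MASS * sum(concentrations.get(name, 0.0) * n
                              for name, n in nitrogen_atoms.items())
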