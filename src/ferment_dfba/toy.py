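"""A hand-built toy yeast network and synthetic fermentation scenarios.

The network is a ~90-reaction, two-compartment (cytoplasm/mitochondrion)
caricature of wine-yeast metabolism carrying every pathway the full-scale
analysis interrogates: lumped glycolysis, the oxidative and non-oxidative
pentose phosphate pathway with the erythritol branch, alcoholic
fermentation, acetate activation to acetyl-CoA and the mevalonate route,
the TCA oxidative branch to 2-oxoglutarate, the cytosolic reductive
branch to succinate, the GABA shunt, Ehrlich routes to isobutanol,
isoamyl alcohol and 2-phenylethanol with parallel NADH/NADPH reductions,
the ethanol–acetaldehyde and glycerol-3-phosphate shuttles, and a
YAN-dependent biomass pseudoreaction.  Formulas track carbon and
nitrogen; cofactors carry inert pseudo-elements so CoA/phosphate
bookkeeping stays closed without hydrogen/oxygen accounting.

Two scenario presets (standard_25C, cold_12C) define complete study
conditions — kinetic parameters, phase schedule and initial must — from
which noisy synthetic datasets with known ground truth are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd

from . import biomass as bm
from . import network
from .kinetics import KineticParameters

LB = network.LARGE_BOUND

# metabolite id -> (name, compartment, formula).  Only C and N are
# balanced; R/X/P are inert bookkeeping elements (redox carrier, CoA,
# phosphate).
_METS = {
    # cytosolic carbon backbone
    "glc_c": ("glucose", "c", "C6"),
    "fru_c": ("fructose", "c", "C6"),
    "g6p_c": ("hexose 6-phosphate", "c", "C6P"),
    "t3p_c": ("triose 3-phosphate", "c", "C3P"),
    "g3p_c": ("glycerol 3-phosphate", "c", "C3P"),
    "glyc_c": ("glycerol", "c", "C3"),
    "pyr_c": ("pyruvate", "c", "C3"),
    "acald_c": ("acetaldehyde", "c", "C2"),
    "etoh_c": ("ethanol", "c", "C2"),
    "ac_c": ("acetate", "c", "C2"),
    "accoa_c": ("acetyl-CoA", "c", "C2X"),
    "coa_c": ("coenzyme A", "c", "X"),
    "aacoa_c": ("acetoacetyl-CoA", "c", "C4X"),
    "hmgcoa_c": ("HMG-CoA", "c", "C6X"),
    "mev_c": ("mevalonate", "c", "C6"),
    "ru5p_c": ("pentose 5-phosphate", "c", "C5P"),
    "e4p_c": ("erythrose 4-phosphate", "c", "C4P"),
    "nmp_c": ("nucleotide monomer", "c", "C5NP"),
    "lip_c": ("lipid (palmitate-like)", "c", "C16"),
    "actn_c": ("acetoin", "c", "C4"),
    "mtl_c": ("mannitol", "c", "C6"),
    "abt_c": ("arabitol", "c", "C5"),
    "btd_c": ("2,3-butanediol", "c", "C4"),
    "oaa_c": ("oxaloacetate", "c", "C4"),
    "mal_c": ("malate", "c", "C4"),
    "fum_c": ("fumarate", "c", "C4"),
    "succ_c": ("succinate", "c", "C4"),
    "akg_c": ("2-oxoglutarate", "c", "C5"),
    "glu_c": ("glutamate", "c", "C5N"),
    "gaba_c": ("4-aminobutanoate", "c", "C4N"),
    "sucsal_c": ("succinate semialdehyde", "c", "C4"),
    "nh4_c": ("ammonium", "c", "N"),
    "aa1_c": ("amino acid pool 1 (glutamate-like)", "c", "C5N"),
    "aa2_c": ("amino acid pool 2 (leucine-like)", "c", "C6N"),
    "aa3_c": ("amino acid pool 3 (phenylalanine-like)", "c", "C9N"),
    "arg_c": ("arginine", "c", "C6N4"),
    "kleu_c": ("ketoleucine", "c", "C6"),
    "mobut_c": ("3-methyl-2-oxobutanoate", "c", "C5"),
    "mbald_c": ("3-methylbutanal", "c", "C5"),
    "ibal_c": ("isobutanal", "c", "C4"),
    "ibol_c": ("isobutanol", "c", "C4"),
    "iaoh_c": ("isoamyl alcohol", "c", "C5"),
    "phpyr_c": ("phenylpyruvate", "c", "C9"),
    "pead_c": ("phenylacetaldehyde", "c", "C8"),
    "peoh_c": ("2-phenylethanol", "c", "C8"),
    "prot_c": ("protein polymer unit", "c", "C5N"),
    "o2_c": ("dissolved oxygen", "c", "O2"),
    "co2_c": ("carbon dioxide", "c", "C"),
    "h2o_c": ("water", "c", "H2O"),
    "h_c": ("proton", "c", "H"),
    "pi_c": ("phosphate", "c", "P"),
    "ppi_c": ("pyrophosphate", "c", "P2"),
    "atp_c": ("ATP", "c", "RP3"),
    "adp_c": ("ADP", "c", "RP2"),
    "amp_c": ("AMP", "c", "RP"),
    "nad_c": ("NAD+", "c", "R"),
    "nadh_c": ("NADH", "c", "RH"),
    "nadp_c": ("NADP+", "c", "RP"),
    "nadph_c": ("NADPH", "c", "RHP"),
    # mitochondrial
    "pyr_m": ("pyruvate", "m", "C3"),
    "acald_m": ("acetaldehyde", "m", "C2"),
    "etoh_m": ("ethanol", "m", "C2"),
    "accoa_m": ("acetyl-CoA", "m", "C2X"),
    "coa_m": ("coenzyme A", "m", "X"),
    "oaa_m": ("oxaloacetate", "m", "C4"),
    "mal_m": ("malate", "m", "C4"),
    "akg_m": ("2-oxoglutarate", "m", "C5"),
    "kleu_m": ("ketoleucine", "m", "C6"),
    "mobut_m": ("3-methyl-2-oxobutanoate", "m", "C5"),
    "ipm_m": ("2-isopropylmalate", "m", "C7"),
    "co2_m": ("carbon dioxide", "m", "C"),
    "nad_m": ("NAD+", "m", "R"),
    "nadh_m": ("NADH", "m", "RH"),
}

# id -> (stoichiometry {met: coef}, reversible, name)
_RXNS = {
    # glycolysis (lumped in three steps so PPP and glycerol can branch)
    "GLK": ({"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, False,
            "hexokinase (glucose)"),
    "FRK": ({"fru_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, False,
            "hexokinase (fructose)"),
    "PFK_ALD": ({"g6p_c": -1, "atp_c": -1, "t3p_c": 2, "adp_c": 1}, False,
                "upper glycolysis (PFK+aldolase+TPI)"),
    "GAPDH_PYK": ({"t3p_c": -1, "nad_c": -1, "adp_c": -2, "pi_c": -1,
                   "pyr_c": 1, "nadh_c": 1, "atp_c": 2, "h2o_c": 1, "h_c": 1},
                  False, "lower glycolysis (GAPDH..PYK)"),
    # glycerol branch + glycerol-3-phosphate shuttle
    "GPD": ({"t3p_c": -1, "nadh_c": -1, "h_c": -1, "g3p_c": 1, "nad_c": 1},
            False, "glycerol-3-phosphate dehydrogenase"),
    "GPP": ({"g3p_c": -1, "h2o_c": -1, "glyc_c": 1, "pi_c": 1}, False,
            "glycerol-3-phosphatase"),
    "G3PSH": ({"g3p_c": -1, "nad_m": -1, "t3p_c": 1, "nadh_m": 1, "h_c": 1},
              False, "glycerol-3-phosphate shuttle"),
    # fermentation
    "PDC": ({"pyr_c": -1, "acald_c": 1, "co2_c": 1}, False,
            "pyruvate decarboxylase"),
    "ADH": ({"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1,
             "nad_c": 1}, True, "alcohol dehydrogenase (cytosolic)"),
    "ALD6": ({"acald_c": -1, "nadp_c": -1, "h2o_c": -1, "ac_c": 1,
              "nadph_c": 1, "h_c": 2}, False,
             "acetaldehyde dehydrogenase (NADP)"),
    # acetate activation, adenylates
    "ACS": ({"ac_c": -1, "atp_c": -1, "coa_c": -1, "accoa_c": 1, "amp_c": 1,
             "ppi_c": 1}, False, "acetyl-CoA synthetase"),
    "PPA": ({"ppi_c": -1, "h2o_c": -1, "pi_c": 2}, False,
            "inorganic pyrophosphatase"),
    "ADK": ({"atp_c": -1, "amp_c": -1, "adp_c": 2}, True,
            "adenylate kinase (cytoplasmic)"),
    # mevalonate route
    "ACACT": ({"accoa_c": -2, "aacoa_c": 1, "coa_c": 1}, False,
              "acetyl-CoA C-acetyltransferase"),
    "HMGS": ({"aacoa_c": -1, "accoa_c": -1, "h2o_c": -1, "hmgcoa_c": 1,
              "coa_c": 1}, False, "HMG-CoA synthase"),
    "HMGR": ({"hmgcoa_c": -1, "nadph_c": -2, "h_c": -2, "mev_c": 1,
              "nadp_c": 2, "coa_c": 1}, False, "HMG-CoA reductase"),
    # pentose phosphate pathway
    "OXPPP": ({"g6p_c": -1, "nadp_c": -2, "h2o_c": -1, "ru5p_c": 1,
               "co2_c": 1, "nadph_c": 2, "h_c": 2}, False,
              "oxidative PPP (G6PDH+GND)"),
    "NOXPPP": ({"ru5p_c": -2, "e4p_c": 1, "g6p_c": 1}, True,
               "non-oxidative PPP (TKL/TAL lump)"),
    # nucleotide and lipid monomers for biomass
    "NMPS": ({"ru5p_c": -1, "nh4_c": -1, "atp_c": -2, "nmp_c": 1,
              "adp_c": 2, "pi_c": 2}, False, "nucleotide monomer synthesis"),
    "LIPS": ({"accoa_c": -8, "nadph_c": -14, "h_c": -14, "atp_c": -7,
              "lip_c": 1, "coa_c": 8, "nadp_c": 14, "adp_c": 7, "pi_c": 7},
             False, "lipid synthesis (palmitate-like)"),
    # overflow/redox valves: butanediol, mannitol, arabitol
    "ALSD": ({"pyr_c": -2, "actn_c": 1, "co2_c": 2}, False,
             "acetolactate synthase + decarboxylase"),
    "BTDD": ({"actn_c": -1, "nadh_c": -1, "h_c": -1, "btd_c": 1,
              "nad_c": 1}, False, "butanediol dehydrogenase"),
    "MTLD": ({"g6p_c": -1, "nadh_c": -1, "h_c": -1, "mtl_c": 1, "nad_c": 1,
              "pi_c": 1}, False, "mannitol synthesis (M1PDH+phosphatase)"),
    "ABTD": ({"ru5p_c": -1, "nadh_c": -1, "h_c": -1, "abt_c": 1, "nad_c": 1,
              "pi_c": 1}, False, "arabitol synthesis (reductase+phosphatase)"),
    # anaplerosis, reductive branch
    "PYC": ({"pyr_c": -1, "co2_c": -1, "atp_c": -1, "oaa_c": 1, "adp_c": 1,
             "pi_c": 1}, False, "pyruvate carboxylase"),
    "MDHc": ({"oaa_c": -1, "nadh_c": -1, "h_c": -1, "mal_c": 1, "nad_c": 1},
             True, "malate dehydrogenase (cytosolic)"),
    "FUMc": ({"mal_c": -1, "fum_c": 1, "h2o_c": 1}, True,
             "fumarase (cytosolic)"),
    "FRDc": ({"fum_c": -1, "nadh_c": -1, "h_c": -1, "succ_c": 1,
              "nad_c": 1}, False, "fumarate reductase (cytosolic)"),
    # mitochondrial oxidative branch to 2-oxoglutarate
    "PYRtm": ({"pyr_c": -1, "pyr_m": 1}, True, "pyruvate transport"),
    "PDHm": ({"pyr_m": -1, "nad_m": -1, "coa_m": -1, "accoa_m": 1,
              "nadh_m": 1, "co2_m": 1}, False, "pyruvate dehydrogenase"),
    "MALtm": ({"mal_c": -1, "mal_m": 1}, True, "malate transport"),
    "MDHm": ({"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1, "h_c": 1},
             True, "malate dehydrogenase (mitochondrial)"),
    "CSIDH": ({"accoa_m": -1, "oaa_m": -1, "nad_m": -1, "h2o_c": -1,
               "akg_m": 1, "co2_m": 1, "nadh_m": 1, "coa_m": 1}, False,
              "citrate synthase..isocitrate dehydrogenase (lump)"),
    "AKGMAL": ({"akg_m": -1, "mal_c": -1, "akg_c": 1, "mal_m": 1}, True,
               "malate/2-oxoglutarate antiporter"),
    # nitrogen assimilation and the GABA shunt
    "GDH1": ({"akg_c": -1, "nh4_c": -1, "nadph_c": -1, "h_c": -1,
              "glu_c": 1, "nadp_c": 1, "h2o_c": 1}, False,
             "glutamate dehydrogenase (NADPH)"),
    "GDH2n": ({"akg_c": -1, "nh4_c": -1, "nadh_c": -1, "h_c": -1,
               "glu_c": 1, "nad_c": 1, "h2o_c": 1}, False,
              "glutamate dehydrogenase (NADH, assimilatory)"),
    "GDHd": ({"glu_c": -1, "nad_c": -1, "h2o_c": -1, "akg_c": 1, "nh4_c": 1,
              "nadh_c": 1, "h_c": 1}, False,
             "glutamate dehydrogenase (deaminating)"),
    "GAD": ({"glu_c": -1, "h_c": -1, "gaba_c": 1, "co2_c": 1}, False,
            "glutamate decarboxylase"),
    "GABAT": ({"gaba_c": -1, "akg_c": -1, "sucsal_c": 1, "glu_c": 1}, False,
              "GABA transaminase"),
    "SSADH": ({"sucsal_c": -1, "nadp_c": -1, "h2o_c": -1, "succ_c": 1,
               "nadph_c": 1, "h_c": 2}, False,
              "succinate-semialdehyde dehydrogenase (NADP)"),
    # respiration, maintenance
    "CO2tm": ({"co2_m": -1, "co2_c": 1}, True, "CO2 transport"),
    "RESP": ({"nadh_m": -1, "o2_c": -0.5, "adp_c": -1.5, "pi_c": -1.5,
              "h_c": -1, "nad_m": 1, "atp_c": 1.5, "h2o_c": 2.5}, False,
             "respiratory chain (P/O 1.5)"),
    "ATPM": ({"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             False, "non-growth ATP maintenance (ATPase)"),
    # ethanol-acetaldehyde shuttle
    "ACALDtm": ({"acald_c": -1, "acald_m": 1}, True,
                "acetaldehyde transport"),
    "ADHm": ({"acald_m": -1, "nadh_m": -1, "h_c": -1, "etoh_m": 1,
              "nad_m": 1}, True, "alcohol dehydrogenase (mitochondrial)"),
    "ETOHtm": ({"etoh_m": -1, "etoh_c": 1}, True, "ethanol transport"),
    # amino-acid uptake fates
    "AA1A": ({"aa1_c": -1, "glu_c": 1}, False, "amino-acid pool 1 entry"),
    "AA2TA": ({"aa2_c": -1, "akg_c": -1, "kleu_c": 1, "glu_c": 1}, False,
              "branched-chain transaminase (pool 2)"),
    "AA2D": ({"aa2_c": -1, "nad_c": -1, "h2o_c": -1, "glu_c": 1, "co2_c": 1,
              "nadh_c": 1}, False, "amino-acid pool 2 oxidative entry"),
    "AA3TA": ({"aa3_c": -1, "akg_c": -1, "phpyr_c": 1, "glu_c": 1}, False,
              "aromatic transaminase (pool 3)"),
    "AA3D": ({"aa3_c": -1, "nad_c": -4, "h2o_c": -4, "glu_c": 1, "co2_c": 4,
              "nadh_c": 4, "h_c": 4}, False,
             "amino-acid pool 3 oxidative entry"),
    "ARGD": ({"arg_c": -1, "h2o_c": -2, "glu_c": 1, "nh4_c": 3, "co2_c": 1},
             False, "arginine degradation (arginase route)"),
    # Ehrlich: valine/isobutanol branch
    "VALS": ({"pyr_m": -2, "nadh_m": -1, "h_c": -1, "mobut_m": 1,
              "co2_m": 1, "nad_m": 1}, False,
             "3-methyl-2-oxobutanoate synthesis (ALS+KARI+DHAD)"),
    "MOBUTt": ({"mobut_m": -1, "mobut_c": 1}, True,
               "3-methyl-2-oxobutanoate transport"),
    "IBDC": ({"mobut_c": -1, "ibal_c": 1, "co2_c": 1}, False,
             "branched-chain decarboxylase (isobutanal)"),
    "IBDHn": ({"ibal_c": -1, "nadh_c": -1, "h_c": -1, "ibol_c": 1,
               "nad_c": 1}, False, "isobutanol dehydrogenase (NADH)"),
    "IBDHp": ({"ibal_c": -1, "nadph_c": -1, "h_c": -1, "ibol_c": 1,
               "nadp_c": 1}, False, "isobutanol dehydrogenase (NADPH)"),
    # Ehrlich: leucine/isoamyl branch
    "IPMS": ({"mobut_m": -1, "accoa_m": -1, "h2o_c": -1, "ipm_m": 1,
              "coa_m": 1}, False, "2-isopropylmalate synthase"),
    "IPMDH": ({"ipm_m": -1, "nad_m": -1, "kleu_m": 1, "co2_m": 1,
               "nadh_m": 1}, False, "isopropylmalate dehydrogenase"),
    "KLEUt": ({"kleu_m": -1, "kleu_c": 1}, True, "ketoleucine transport"),
    "KDC": ({"kleu_c": -1, "mbald_c": 1, "co2_c": 1}, False,
            "ketoleucine decarboxylase (3-methylbutanal)"),
    "IAMDHn": ({"mbald_c": -1, "nadh_c": -1, "h_c": -1, "iaoh_c": 1,
                "nad_c": 1}, False, "isoamyl alcohol dehydrogenase (NADH)"),
    "IAMDHp": ({"mbald_c": -1, "nadph_c": -1, "h_c": -1, "iaoh_c": 1,
                "nadp_c": 1}, False,
               "isoamyl alcohol dehydrogenase (NADPH)"),
    # Ehrlich: 2-phenylethanol branch
    "PHES": ({"e4p_c": -1, "pyr_c": -2, "nadph_c": -1, "atp_c": -1,
              "phpyr_c": 1, "co2_c": 1, "nadp_c": 1, "adp_c": 1, "pi_c": 1},
             False, "phenylpyruvate synthesis (shikimate lump)"),
    "PPDC": ({"phpyr_c": -1, "pead_c": 1, "co2_c": 1}, False,
             "phenylpyruvate decarboxylase"),
    "PEADHn": ({"pead_c": -1, "nadh_c": -1, "h_c": -1, "peoh_c": 1,
                "nad_c": 1}, False, "phenylethanol dehydrogenase (NADH)"),
    "PEADHp": ({"pead_c": -1, "nadph_c": -1, "h_c": -1, "peoh_c": 1,
                "nadp_c": 1}, False, "phenylethanol dehydrogenase (NADPH)"),
    # protein turnover (stationary objective flux)
    "PROTSYN": ({"glu_c": -1, "atp_c": -4.3, "h2o_c": -4.3, "prot_c": 1,
                 "adp_c": 4.3, "pi_c": 4.3}, False,
                "protein polymerization pseudo-flux"),
    "PROTDEG": ({"prot_c": -1, "h2o_c": -1, "glu_c": 1}, False,
                "protein degradation"),
    "SK_prot_c": ({"prot_c": -1}, False, "protein accumulation sink"),
}

# exchanged species: metabolite -> (default lb, default ub)
_EXCHANGES = {
    "glc_c": (-10.0, 0.0),
    "fru_c": (-10.0, 0.0),
    "nh4_c": (-10.0, 0.0),
    "aa1_c": (-10.0, 0.0),
    "aa2_c": (-10.0, 0.0),
    "aa3_c": (-10.0, 0.0),
    "arg_c": (-10.0, 0.0),
    "o2_c": (-10.0, 0.0),
    "etoh_c": (0.0, LB),
    "glyc_c": (0.0, LB),
    "btd_c": (0.0, LB),
    "acald_c": (0.0, LB),   # acetaldehyde overflow, redox-neutral valve
    "mtl_c": (0.0, LB),
    "abt_c": (0.0, LB),
    "succ_c": (0.0, LB),
    "ac_c": (0.0, LB),
    "ibol_c": (0.0, LB),
    "iaoh_c": (0.0, LB),
    "peoh_c": (0.0, LB),
    "mev_c": (0.0, 0.0),       # opened for the stationary phase only
    "co2_c": (-LB, LB),
    "h2o_c": (-LB, LB),
    "h_c": (-LB, LB),
    "pi_c": (-LB, LB),
}


def exchange_id(met_id: str) -> str:
    return f"EX_{met_id.rsplit('_', 1)[0]}_e"


def build_toy_model(with_erythritol: bool = True,
                    composition: bm.BiomassComposition | None = None,
                    gam: bm.GamBreakdown | None = None) -> cobra.Model:
    """Construct the toy network as a cobra model.

    The biomass pseudoreaction (BIOMASS) and its carbohydrate-enriched
    variant (BIOMASS_CARB) are installed with the given composition/GAM
    (defaults: protein 0.41 composition, GAM_F 60).
    """
    model = cobra.Model("toy_yeast")
    model.compartments = {"c": "cytoplasm", "m": "mitochondrion",
                          "e": "extracellular"}
    mets = {}
    for mid, (name, comp, formula) in _METS.items():
        mets[mid] = cobra.Metabolite(mid, name=name, compartment=comp,
                                     formula=formula)
    model.add_metabolites(list(mets.values()))
    rxns = []
    for rid, (stoich, rev, name) in _RXNS.items():
        r = cobra.Reaction(rid, name=name,
                           lower_bound=-LB if rev else 0.0, upper_bound=LB)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        rxns.append(r)
    for mid, (lo, hi) in _EXCHANGES.items():
        r = cobra.Reaction(exchange_id(mid), name=f"{mets[mid].name} exchange",
                           lower_bound=lo, upper_bound=hi)
        r.add_metabolites({mets[mid]: -1.0})
        rxns.append(r)
    # biomass pseudoreactions (coefficients filled below)
    for rid in ("BIOMASS", "BIOMASS_CARB"):
        r = cobra.Reaction(rid, name=rid.replace("_", " ").lower(),
                           lower_bound=0.0, upper_bound=LB)
        rxns.append(r)
    model.add_reactions(rxns)
    model.biomass_reaction_id = "BIOMASS"

    comp = composition or bm.compose_biomass(0.41)
    g = gam or bm.total_gam(comp, gam_f=60.0)
    precursors = bm.PrecursorMap.default()
    bm.update_biomass_reaction(model, comp, g, precursors, "BIOMASS")
    comp_carb = bm.carb_shifted(comp)
    g_carb = bm.total_gam(comp_carb, gam_f=g.gam_f)
    bm.update_biomass_reaction(model, comp_carb, g_carb, precursors,
                               "BIOMASS_CARB")
    model.objective = "BIOMASS"
    if with_erythritol:
        model = network.add_erythritol_pathway(model)
        model.biomass_reaction_id = "BIOMASS"
    return model


def write_toy_sbml(path, **kwargs):
    network.save_sbml(build_toy_model(**kwargs), path)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

#: maps extracellular state names to toy exchange reaction ids
SPECIES_EXCHANGES = {
    "glucose": "EX_glc_e",
    "fructose": "EX_fru_e",
    "ammonium": "EX_nh4_e",
    "aa1": "EX_aa1_e",
    "aa2": "EX_aa2_e",
    "aa3": "EX_aa3_e",
    "arginine": "EX_arg_e",
    "oxygen": "EX_o2_e",
    "ethanol": "EX_etoh_e",
    "glycerol": "EX_glyc_e",
    "succinate": "EX_succ_e",
    "acetate": "EX_ac_e",
    "erythritol": "EX_erythritol_e",
    "isobutanol": "EX_ibol_e",
    "isoamyl_alcohol": "EX_iaoh_e",
    "phenylethanol": "EX_peoh_e",
}

#: nitrogen atoms per molecule for YAN bookkeeping
NITROGEN_ATOMS = {"ammonium": 1, "aa1": 1, "aa2": 1, "aa3": 1, "arginine": 4}

#: initial must, mM except dry weight (gDW/L); shared by both temperatures
INITIAL_MUST = {
    "glucose": 555.0,
    "fructose": 555.0,
    "ammonium": 2.0,
    "aa1": 1.2,
    "aa2": 0.6,
    "aa3": 0.5,
    "arginine": 1.0,
    "oxygen": 0.25,
    "ethanol": 0.0,
    "glycerol": 0.0,
    "succinate": 0.0,
    "acetate": 0.0,
    "erythritol": 0.0,
    "isobutanol": 0.0,
    "isoamyl_alcohol": 0.0,
    "phenylethanol": 0.0,
    "DW": 0.05,
}


@dataclass
class ScenarioPreset:
    """A complete simulated study condition with known ground truth."""

    name: str
    params: KineticParameters
    schedule: "PhaseSchedule"  # noqa: F821 - engine import kept lazy
    initial_state: dict
    protein_curve: bm.ProteinCurve
    lipid_excretion: tuple = ("mev_c",)
    rho: float = 0.05
    dna_fraction: float = 0.01
    lipid_fraction: float = 0.05

    def initial_yan(self) -> float:
        return bm.yan_of_state(self.initial_state, NITROGEN_ATOMS)


def _gam_f_for_total(total: float, protein0: float) -> float:
    """Back out GAM_F from a target total GAM at the initial composition."""
    comp = bm.compose_biomass(protein0)
    poly = bm.total_gam(comp, gam_f=0.0).total
    return total - poly


def _make_preset(name, schedule, curve_p0, total_gam, kin_kwargs):
    from .engine import PhaseSchedule  # lazy: engine imports kinetics

    yan0 = bm.yan_of_state(INITIAL_MUST, NITROGEN_ATOMS)
    curve = bm.ProteinCurve.calibrated(p_min=0.25, k_p=50.0, yan0=yan0,
                                       p0=curve_p0)
    kin_kwargs = dict(kin_kwargs)
    kin_kwargs["gam_f"] = _gam_f_for_total(total_gam, curve_p0)
    params = KineticParameters(**kin_kwargs)
    return ScenarioPreset(name=name, params=params,
                          schedule=PhaseSchedule(*schedule),
                          initial_state=dict(INITIAL_MUST),
                          protein_curve=curve)


def standard_25C() -> ScenarioPreset:
    """Near-optimal temperature scenario: fast phases, strong acetate
    uptake and succinate production, low erythritol."""
    return _make_preset(
        "standard_25C", schedule=(5.0, 40.0, 90.0, 210.0, 300.0),
        curve_p0=0.41, total_gam=99.8,
        kin_kwargs=dict(
            vmax_G=3.5, k_G=20.0, vmax_F=2.5, k_F=25.0, K_Ei=450.0,
            vmax_NH4=0.4, k_NH4=0.3,
            k_AA={"aa1": 0.030, "aa2": 0.020, "aa3": 0.015},
            k_Arg=0.020, k_O2=1.0,
            k_P={"ethanol": 1.58, "glycerol": 0.18, "succinate": 0.008,
                 "acetate": 0.020, "erythritol": 0.002, "isobutanol": 0.0008,
                 "isoamyl_alcohol": 0.0012, "phenylethanol": 0.0004},
            X_A=1.0, k_acetate_uptake=0.010, k_d=0.004))


def cold_12C() -> ScenarioPreset:
    """Cold scenario: slower kinetics, longer phases, higher GAM and
    initial protein content, more erythritol, weak acetate uptake."""
    return _make_preset(
        "cold_12C", schedule=(15.0, 100.0, 200.0, 420.0, 600.0),
        curve_p0=0.66, total_gam=137.0,
        kin_kwargs=dict(
            vmax_G=2.0, k_G=20.0, vmax_F=1.4, k_F=25.0, K_Ei=500.0,
            vmax_NH4=0.12, k_NH4=0.3,
            k_AA={"aa1": 0.008, "aa2": 0.006, "aa3": 0.004},
            k_Arg=0.006, k_O2=0.5,
            k_P={"ethanol": 1.55, "glycerol": 0.19, "succinate": 0.004,
                 "acetate": 0.012, "erythritol": 0.006, "isobutanol": 0.001,
                 "isoamyl_alcohol": 0.002, "phenylethanol": 0.0005},
            X_A=1.0, k_acetate_uptake=0.002, k_d=0.002))


PRESETS = {"standard_25C": standard_25C, "cold_12C": cold_12C}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name}; choose from {list(PRESETS)}")


# ---------------------------------------------------------------------------
# synthetic datasets
# ---------------------------------------------------------------------------

def generate_dataset(preset: ScenarioPreset, noise_cv: float, seed: int,
                     sampling_times=None, solver_options=None,
                     trajectory=None):
    """Simulate a preset and sample noisy measurements from it.

    Noise is multiplicative lognormal with the requested coefficient of
    variation, independent per observation and mean-preserving.  Returns
    (long-format DataFrame with columns variable/time_h/value, ground
    truth Trajectory).
    """
    from .engine import DfbaProblem, SolverOptions

    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if trajectory is None:
        opts = solver_options or SolverOptions()
        trajectory = DfbaProblem.from_preset(preset).simulate(options=opts)
    traj = trajectory
    if sampling_times is None:
        sampling_times = np.linspace(0.0, preset.schedule.t_end, 25)[1:]
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    rows = []
    for var in traj.state_names:
        clean = np.interp(sampling_times, traj.times, traj.state(var))
        if noise_cv > 0:
            factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                        size=clean.shape))
        else:
            factors = np.ones_like(clean)
        for t, v in zip(sampling_times, clean * factors):
            rows.append((var, float(t), float(v)))
    df = pd.DataFrame(rows, columns=["variable", "time_h", "value"])
    return df, traj
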