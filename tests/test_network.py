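"""Model I/O, curation edits and stoichiometric yield queries."""

import cobra
import numpy as np
import pytest
from cobra.util.array import create_stoichiometric_matrix

from ferment_dfba import network, toy
from ferment_dfba.network import (ModelError, add_erythritol_pathway,
                                  check_mass_balance, load_sbml,
                                  open_excretion, pathway_yield,
                                  remove_reactions, save_sbml)


def _stoich_dict(model):
    return {r.id: {m.id: c for m, c in r.metabolites.items()}
            for r in model.reactions}


class TestSbmlRoundTrip:
    def test_write_then_read_preserves_stoichiometry(self, toy_model,
                                                     tmp_path):
        path = tmp_path / "toy.xml"
        save_sbml(toy_model, path)
        back = load_sbml(path)
        assert len(back.reactions) == len(toy_model.reactions)
        sd_a, sd_b = _stoich_dict(back), _stoich_dict(toy_model)
        assert sd_a.keys() == sd_b.keys()
        for rid in sd_a:
            assert sd_a[rid].keys() == sd_b[rid].keys()
            for mid in sd_a[rid]:
                # SBML serializes doubles at ~15 significant digits
                assert sd_a[rid][mid] == pytest.approx(sd_b[rid][mid],
                                                       rel=1e-12)
        for rid in ("GLK", "EX_glc_e", "BIOMASS"):
            a, b = toy_model.reactions.get_by_id(rid), \
                back.reactions.get_by_id(rid)
            assert a.bounds == b.bounds

    def test_empty_model_rejected(self, tmp_path):
        path = tmp_path / "empty.xml"
        cobra.io.write_sbml_model(cobra.Model("nothing"), str(path))
        with pytest.raises(ModelError, match="no reactions"):
            load_sbml(path)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<sbml>not really</sbml>")
        with pytest.raises(ModelError):
            load_sbml(path)


class TestRemoveReactions:
    def test_empty_list_is_identity(self, toy_model):
        out = remove_reactions(toy_model, [])
        assert _stoich_dict(out) == _stoich_dict(toy_model)

    def test_removal_drops_column_and_keeps_orphans(self, toy_model):
        out = remove_reactions(toy_model, ["GAD", "GAD"])  # dupes allowed
        assert len(out.reactions) == len(toy_model.reactions) - 1
        assert "GAD" not in [r.id for r in out.reactions]
        # metabolites are retained even if now orphaned
        assert len(out.metabolites) == len(toy_model.metabolites)

    def test_unknown_ids_abort_without_partial_removal(self, toy_model):
        with pytest.raises(KeyError, match="nope1.*nope2"):
            remove_reactions(toy_model, ["GAD", "nope1", "nope2"])

    def test_remove_then_readd_restores_matrix(self, toy_model):
        rid = "GABAT"
        rxn = toy_model.reactions.get_by_id(rid)
        out = remove_reactions(toy_model, [rid])
        copy_rxn = cobra.Reaction(rid, lower_bound=rxn.lower_bound,
                                  upper_bound=rxn.upper_bound)
        copy_rxn.add_metabolites(
            {out.metabolites.get_by_id(m.id): c
             for m, c in rxn.metabolites.items()})
        out.add_reactions([copy_rxn])
        assert _stoich_dict(out) == _stoich_dict(toy_model)


class TestErythritolPathway:
    def test_adds_three_reactions_with_fixed_ids(self):
        base = toy.build_toy_model(with_erythritol=False)
        out = add_erythritol_pathway(base)
        assert len(out.reactions) == len(base.reactions) + 3
        for rid in ("ery1", "ery2", "EX_erythritol_e"):
            assert rid in [r.id for r in out.reactions]
        ery2 = out.reactions.get_by_id("ery2")
        # exactly one NADPH consumed per erythritol
        assert ery2.metabolites[out.metabolites.get_by_id("nadph_c")] == -1
        assert ery2.metabolites[out.metabolites.get_by_id("eryol_c")] == 1

    def test_idempotent(self, toy_model):
        with pytest.warns(UserWarning, match="already present"):
            twice = add_erythritol_pathway(toy_model)
        assert len(twice.reactions) == len(toy_model.reactions)

    def test_missing_prerequisite_is_named(self):
        base = toy.build_toy_model(with_erythritol=False)
        nadp = base.metabolites.get_by_id("nadp_c")
        base.remove_metabolites([nadp], destructive=True)
        with pytest.raises(ModelError, match="NADP"):
            add_erythritol_pathway(base)


class TestOpenExcretion:
    def test_opens_export_and_closes_import(self, toy_model):
        out = open_excretion(toy_model, ["mev_c"])
        ex = out.reactions.get_by_id("EX_mev_e")
        assert ex.bounds == (0.0, 1000.0)

    def test_empty_list_identity(self, toy_model):
        out = open_excretion(toy_model, [])
        assert _stoich_dict(out) == _stoich_dict(toy_model)

    def test_idempotent_on_open_exchange(self, toy_model):
        once = open_excretion(toy_model, ["etoh_c"])
        twice = open_excretion(once, ["etoh_c"])
        assert twice.reactions.get_by_id("EX_etoh_e").bounds == \
            once.reactions.get_by_id("EX_etoh_e").bounds

    def test_unknown_species_rejected(self, toy_model):
        with pytest.raises(KeyError):
            open_excretion(toy_model, ["unobtainium_c"])


class TestPathwayYield:
    def test_mevalonate_costs_three_acetate_two_nadph(self, toy_model):
        res = pathway_yield(toy_model, "ac_c", "mev_c",
                            tracked_cofactor="nadph_c")
        assert res.yield_per_substrate == pytest.approx(1 / 3, abs=1e-9)
        assert res.substrate_per_product == pytest.approx(3.0, abs=1e-8)
        assert res.cofactor_per_product == pytest.approx(2.0, abs=1e-8)

    def test_gaba_shunt_produces_one_nadph_per_succinate(self, toy_model):
        res = pathway_yield(toy_model, "akg_c", "succ_c",
                            tracked_cofactor="nadph_c")
        assert res.yield_per_substrate == pytest.approx(1.0, abs=1e-9)
        # negative consumption = net production of one NADPH per succinate
        assert res.cofactor_per_product == pytest.approx(-1.0, abs=1e-8)

    def test_identity_path(self, toy_model):
        assert pathway_yield(toy_model, "glc_c",
                             "glc_c").yield_per_substrate == 1.0

    def test_no_route_reports_zero_yield(self, toy_model):
        res = pathway_yield(toy_model, "glyc_c", "glc_c")
        assert res.yield_per_substrate == 0.0
        assert "no" in res.diagnostic

    def test_agrees_with_cobra_oracle(self, toy_model):
        """Independent check of the mevalonate yield through cobrapy."""
        work = toy_model.copy()
        for rxn in work.reactions:
            if rxn.boundary:
                rxn.bounds = (0.0, 0.0)
        for sid in network.DEFAULT_OPEN_SINKS:
            if sid in work.metabolites:
                met = work.metabolites.get_by_id(sid)
                for rxn in met.reactions:
                    if rxn.boundary:
                        rxn.bounds = (-1000.0, 1000.0)
        for red, ox in network.DEFAULT_FREE_PAIRS:
            r = cobra.Reaction(f"free_{red}", lower_bound=-1000,
                               upper_bound=1000)
            r.add_metabolites({work.metabolites.get_by_id(ox): -1,
                               work.metabolites.get_by_id(red): 1})
            work.add_reactions([r])
        work.reactions.get_by_id("EX_ac_e").bounds = (-1.0, -1.0)
        work.reactions.get_by_id("EX_mev_e").bounds = (0.0, 1000.0)
        work.objective = "EX_mev_e"
        sol = work.optimize()
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(1 / 3, abs=1e-8)


class TestMassBalance:
    def test_toy_network_is_carbon_and_nitrogen_balanced(self, toy_model):
        assert check_mass_balance(toy_model, elements=("C", "N")) == {}

    def test_detects_broken_stoichiometry(self, toy_model):
        broken = toy_model.copy()
        rxn = broken.reactions.get_by_id("PDC")
        rxn.add_metabolites({broken.metabolites.get_by_id("co2_c"): 1.0})
        bad = check_mass_balance(broken, elements=("C",))
        assert "PDC" in bad
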