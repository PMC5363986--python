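import itertools

import numpy as np
import pytest

import notchwnt as nw
from notchwnt.errors import InputError
from notchwnt.network import Reaction, ReactionNetwork

P = nw.default_params()


def small_net(reactions, species=None):
    if species is None:
        seen = []
        for r in reactions:
            for sp, _ in r.reactants + r.products:
                if sp not in seen:
                    seen.append(sp)
            for sp in r.promoters + r.inhibitors:
                if sp not in seen:
                    seen.append(sp)
        species = seen
    return ReactionNetwork(species=species, reactions=list(reactions))


class TestBuildNetwork:
    def test_full_variant_covers_all_twelve_species(self):
        net = nw.build_network("full", "step4_and_14", "on")
        assert sorted(net.species) == sorted(nw.SPECIES)
        labels = [r.label for r in net.reactions]
        # the 14 regulated/conversion steps plus first-order decays
        assert len([l for l in labels if not l.startswith("decay_")]) == 14
        assert len([l for l in labels if l.startswith("decay_")]) == 9

    def test_coupling_choice_toggles_promoter_annotation(self):
        both = nw.build_network("full", "step4_and_14", "on")
        only4 = nw.build_network("full", "step4_only", "on")
        h_both = next(r for r in both.reactions if r.label == "hes1_production")
        h_only = next(r for r in only4.reactions if r.label == "hes1_production")
        assert h_both.promoters == ("B", "I1")
        assert h_only.promoters == ("I1",)

    def test_notch_only_keeps_beta_catenin_as_io_reactant(self):
        net = nw.build_network("notch_only", "step4_and_14", "on")
        assert "B" in net.species and "G" not in net.species
        labels = {r.label for r in net.reactions}
        assert {"bcat_inflow", "bcat_outflow", "nicd_bcat_binding"} <= labels

    def test_wnt_flag_adds_stimulated_production(self):
        on = nw.build_network("wnt_only", None, "on")
        off = nw.build_network("wnt_only", None, "off")
        assert any(r.label == "bcat_production_wnt" for r in on.reactions)
        assert not any(r.label == "bcat_production_wnt" for r in off.reactions)

    def test_invalid_combinations_rejected(self):
        with pytest.raises(InputError):
            nw.build_network("wnt_only", "step4_only", "on")
        with pytest.raises(InputError):
            nw.build_network("full", None, "on")
        with pytest.raises(InputError):
            nw.build_network("sideways", "step4_only", "on")


class TestStoichiometry:
    def test_simple_conversion_column(self):
        net = small_net([Reaction.make({"A": 1}, {"B": 1})])
        S = nw.stoichiometric_matrix(net)
        assert S.tolist() == [[-1], [1]]

    def test_stoichiometric_coefficient_two(self):
        net = small_net([Reaction.make({"A": 2}, {"C": 1})], species=["A", "B", "C"])
        S = nw.stoichiometric_matrix(net)
        assert S[:, 0].tolist() == [-2, 0, 1]

    def test_full_model_rank_respects_conservation_laws(self):
        net = nw.build_network("full", "step4_and_14", "on")
        S = nw.stoichiometric_matrix(net)
        rank = np.linalg.matrix_rank(S)
        # one conserved quantity: the closed GSK pool G + C + I2
        assert rank == len(net.species) - 1


def brute_force_conservative(S, grid=(0.25, 0.5, 1.0, 2.0, 4.0)):
    """Tiny-network oracle: search a positive grid for a mass vector."""
    n = S.shape[0]
    for combo in itertools.product(grid, repeat=n):
        if np.allclose(np.asarray(combo) @ S, 0.0, atol=1e-9):
            return True
    return False


class TestConservativity:
    def test_reversible_isomerisation_is_conservative(self):
        net = small_net([Reaction.make({"A": 1}, {"B": 1}),
                         Reaction.make({"B": 1}, {"A": 1})])
        assert nw.is_conservative(net)

    def test_open_inflow_outflow_is_not(self):
        net = small_net([Reaction.make({}, {"A": 1}),
                         Reaction.make({"A": 1}, {})])
        assert not nw.is_conservative(net)

    def test_gsk_subnetwork_conserves_mass(self):
        net = small_net([
            Reaction.make({"G": 1}, {"C": 1}),
            Reaction.make({"C": 1}, {"G": 1}),
            Reaction.make({"C": 1, "B": 1}, {"I2": 1}),
            Reaction.make({"I2": 1}, {"C": 1}),
            Reaction.make({}, {"B": 1}),
            Reaction.make({"B": 1}, {}),
        ])
        # restricted to (G, C, I2) mass can balance; full net with open B cannot
        gsk = small_net([
            Reaction.make({"G": 1}, {"C": 1}),
            Reaction.make({"C": 1}, {"G": 1}),
            Reaction.make({"C": 1}, {"I2": 1}),
            Reaction.make({"I2": 1}, {"C": 1}),
        ])
        assert nw.is_conservative(gsk)
        assert not nw.is_conservative(net)

    @pytest.mark.parametrize("variant, coupling", [
        ("notch_only", "step4_only"), ("wnt_only", None), ("full", "step4_and_14"),
    ])
    def test_agrees_with_brute_force_on_small_restrictions(self, variant, coupling):
        net = nw.build_network(variant, coupling, "on")
        S = nw.stoichiometric_matrix(net)
        if S.shape[0] <= 6:
            assert nw.is_conservative(net) == brute_force_conservative(S)
        else:
            # decaying species preclude a global mass vector
            assert not nw.is_conservative(net)


class TestWeakReversibility:
    def test_two_way_conversion(self):
        net = small_net([Reaction.make({"A": 1}, {"B": 1}),
                         Reaction.make({"B": 1}, {"A": 1})])
        assert nw.is_weakly_reversible(net)

    def test_linear_chain_is_not(self):
        net = small_net([Reaction.make({"A": 1}, {"B": 1}),
                         Reaction.make({"B": 1}, {"C": 1})])
        assert not nw.is_weakly_reversible(net)

    def test_brute_force_path_check_on_small_nets(self):
        import networkx as nx
        from notchwnt.network import _complex_key
        for rxns in ([Reaction.make({"A": 1}, {"B": 1}),
                      Reaction.make({"B": 1}, {"C": 1}),
                      Reaction.make({"C": 1}, {"A": 1})],
                     [Reaction.make({"A": 1}, {"B": 1}),
                      Reaction.make({"B": 1}, {"C": 1})],
                     [Reaction.make({"A": 1, "B": 1}, {"C": 2}),
                      Reaction.make({"C": 2}, {"A": 1, "B": 1}),
                      Reaction.make({"D": 1}, {"E": 1}),
                      Reaction.make({"E": 1}, {"D": 1})]):
            net = small_net(rxns)
            G = nx.DiGraph()
            for r in net.reactions:
                G.add_edge(_complex_key(r.reactants), _complex_key(r.products))
            und = G.to_undirected()
            brute = all(
                nx.has_path(G, u, v)
                for u in G.nodes for v in G.nodes
                if u != v and nx.has_path(und, u, v))
            assert nw.is_weakly_reversible(net) == brute

    def test_full_model_verdict_is_computed_not_asserted(self):
        net = nw.build_network("full", "step4_and_14", "on")
        verdict = nw.is_weakly_reversible(net)
        assert isinstance(verdict, bool)
        # with one-way decays to the empty complex the graph cannot return
        assert verdict is False


class TestToolboxDialect:
    def test_binding_reaction_renders_plainly(self):
        net = small_net([Reaction.make({"F": 1, "B": 1}, {"I1": 1})])
        text = nw.export_crn_toolbox(net)
        assert "B + F -> I1" in text

    def test_influences_annotate_the_arrow(self):
        net = small_net([Reaction.make({}, {"H1": 1}, promoters=["I1", "B"],
                                       inhibitors=["H1"])])
        text = nw.export_crn_toolbox(net)
        assert "0 -(+B, +I1, -H1)-> H1" in text

    @pytest.mark.parametrize("variant, coupling, wnt", [
        ("notch_only", "step4_only", "on"),
        ("notch_only", "step4_and_14", "off"),
        ("wnt_only", None, "on"),
        ("wnt_only", None, "off"),
        ("full", "step4_only", "off"),
        ("full", "step4_and_14", "on"),
    ])
    def test_export_parse_roundtrip(self, variant, coupling, wnt):
        net = nw.build_network(variant, coupling, wnt)
        assert nw.parse_crn_toolbox(nw.export_crn_toolbox(net)) == net

    def test_reserved_characters_in_names_rejected(self):
        net = ReactionNetwork(species=["A+?"], reactions=[
            Reaction.make({"A+?": 1}, {})])
        with pytest.raises(InputError):
            nw.export_crn_toolbox(net)


class TestProbePlumbing:
    def test_invalid_arguments(self):
        with pytest.raises(InputError):
            nw.multistability_probe("wnt_only", "step4_only", "on")
        with pytest.raises(InputError):
            nw.multistability_probe("full", None, "on")
        with pytest.raises(InputError):
            nw.multistability_probe("full", "step4_only", "on", n_parameter_draws=0)

    def test_wnt_only_base_draw_is_monostable(self):
        res = nw.multistability_probe("wnt_only", None, "on",
                                      n_parameter_draws=3, n_starts=15, seed=0)
        assert res.verdict == "monostable"
        assert res.caveat is not None  # one-sided evidence flag

    def test_probe_is_seed_reproducible(self):
        a = nw.multistability_probe("notch_only", "step4_only", "on",
                                    n_parameter_draws=4, n_starts=10, seed=9)
        b = nw.multistability_probe("notch_only", "step4_only", "on",
                                    n_parameter_draws=4, n_starts=10, seed=9)
        assert a.verdict == b.verdict and a.n_draws == b.n_draws
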