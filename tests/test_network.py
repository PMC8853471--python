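"""Network data model, format round-trips, splitting, and media application."""

import json

import numpy as np
import pytest

from canyuns.network import (
    FORWARD,
    REVERSE,
    MediaCondition,
    MediaError,
    Metabolite,
    NetworkValidationError,
    Reaction,
    UniversalNetwork,
    apply_media,
    parse_formula,
    read_network,
    split_reversible,
    write_network,
)
from canyuns.dgfba import fba_growth

from helpers import make_network, two_route_network


def toy_network():
    net, _, _ = two_route_network()
    # make one reaction reversible so round-trips cover negative bounds
    net.reactions["Q1"].lower_bound = -1000.0
    return net


def assert_networks_equal(a: UniversalNetwork, b: UniversalNetwork, kinds=True):
    assert set(a.reactions) == set(b.reactions)
    assert set(a.metabolites) == set(b.metabolites)
    for rid, rxn in a.reactions.items():
        other = b.reactions[rid]
        assert rxn.stoichiometry == other.stoichiometry
        assert rxn.lower_bound == other.lower_bound
        assert rxn.upper_bound == other.upper_bound
        if kinds:
            assert rxn.kind == other.kind
    for mid, met in a.metabolites.items():
        assert met.compartment == b.metabolites[mid].compartment
        assert met.formula == b.metabolites[mid].formula
    assert a.biomass_id == b.biomass_id


class TestFormulas:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("X", {"X": 1}),
            ("CH4", {"C": 1, "H": 4}),
            (None, None),
        ],
    )
    def test_parse(self, text, counts):
        assert parse_formula(text) == counts

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_formula("6CH")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["json", "sbml"])
    def test_write_read_identity(self, fmt, tmp_path):
        net = toy_network()
        path = tmp_path / f"net.{'json' if fmt == 'json' else 'xml'}"
        write_network(net, path, format=fmt)
        back = read_network(path, format=fmt, biomass_id="BIOMASS")
        assert_networks_equal(net, back)

    def test_json_and_sbml_parse_identically(self, tmp_path):
        net = toy_network()
        write_network(net, tmp_path / "net.json", format="json")
        write_network(net, tmp_path / "net.xml", format="sbml")
        from_json = read_network(tmp_path / "net.json")
        from_sbml = read_network(tmp_path / "net.xml", biomass_id="BIOMASS")
        assert_networks_equal(from_json, from_sbml)

    def test_dangling_metabolite_rejected(self, tmp_path):
        net = toy_network()
        blob = json.loads((lambda: (write_network(net, tmp_path / "n.json"),
                                    (tmp_path / "n.json").read_text())[1])())
        blob["reactions"][0]["stoichiometry"] = {"ghost_c": -1.0}
        (tmp_path / "bad.json").write_text(json.dumps(blob))
        with pytest.raises(NetworkValidationError, match="undeclared metabolite"):
            read_network(tmp_path / "bad.json")

    def test_empty_stoichiometry_rejected_before_write(self, tmp_path):
        net = toy_network()
        net.reactions["P"].stoichiometry = {}
        with pytest.raises(NetworkValidationError, match="empty stoichiometry"):
            write_network(net, tmp_path / "n.json")

    def test_missing_biomass_rejected(self, tmp_path):
        net = toy_network()
        write_network(net, tmp_path / "net.xml", format="sbml")
        with pytest.raises(NetworkValidationError, match="biomass"):
            read_network(tmp_path / "net.xml", biomass_pattern="nosuchpattern")


class TestSplit:
    def test_reversible_reaction_yields_two_components(self):
        net = toy_network()
        split = split_reversible(net)
        comps = split.components_of("Q1")
        assert set(comps) == {FORWARD, REVERSE}
        assert comps[FORWARD].upper_bound == 1000.0
        assert comps[REVERSE].upper_bound == 1000.0
        assert comps[REVERSE].stoichiometry == {
            m: -c for m, c in net.reactions["Q1"].stoichiometry.items()
        }

    def test_irreversible_reaction_passes_through(self):
        net = toy_network()
        split = split_reversible(net)
        assert set(split.components_of("P")) == {FORWARD}

    def test_mapping_total_and_invertible(self):
        split = split_reversible(toy_network())
        seen = {}
        for cid, (base, direction) in split.mapping.items():
            assert (base, direction) not in seen.values()
            seen[cid] = (base, direction)
        assert {b for b, _ in seen.values()} == set(split.base.reactions)

    def test_split_fluxes_recombine_to_base_mass_balance(self):
        """Any feasible split flux vector must satisfy S v = 0 on the base."""
        from scipy.optimize import linprog

        net = toy_network()
        split = split_reversible(net)
        S, met_ids, comp_ids = split.matrix()
        ub = np.array([split.components[c].upper_bound for c in comp_ids])
        Sbase, base_mets, base_rxns = net.stoichiometric_matrix()
        rng = np.random.default_rng(11)
        for _ in range(20):
            res = linprog(
                c=rng.normal(size=len(comp_ids)),
                A_eq=S, b_eq=np.zeros(len(met_ids)),
                bounds=np.column_stack([np.zeros(len(comp_ids)), ub]),
                method="highs",
            )
            assert res.status == 0
            net_flux = split.net_fluxes(dict(zip(comp_ids, res.x)))
            v = np.array([net_flux[r] for r in base_rxns])
            assert np.allclose(Sbase @ v, 0.0, atol=1e-8)
            # and the recombined vector respects the base bounds
            for rid, value in net_flux.items():
                rxn = net.reactions[rid]
                assert rxn.lower_bound - 1e-8 <= value <= rxn.upper_bound + 1e-8

    def test_base_feasible_vector_has_split_representation(self):
        from scipy.optimize import linprog

        net = toy_network()
        S, met_ids, rxn_ids = net.stoichiometric_matrix()
        lb = np.array([net.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([net.reactions[r].upper_bound for r in rxn_ids])
        split = split_reversible(net)
        rng = np.random.default_rng(5)
        for _ in range(20):
            res = linprog(
                c=rng.normal(size=len(rxn_ids)),
                A_eq=S, b_eq=np.zeros(len(met_ids)),
                bounds=np.column_stack([lb, ub]), method="highs",
            )
            assert res.status == 0
            for rid, value in zip(rxn_ids, res.x):
                comps = split.components_of(rid)
                fwd = max(value, 0.0)
                rev = max(-value, 0.0)
                if fwd > 1e-9:
                    assert FORWARD in comps and fwd <= comps[FORWARD].upper_bound + 1e-7
                if rev > 1e-9:
                    assert REVERSE in comps and rev <= comps[REVERSE].upper_bound + 1e-7


class TestMedia:
    def test_listed_uptake_opened_rest_closed(self):
        net, media, _ = two_route_network()
        constrained = apply_media(split_reversible(net), media)
        assert constrained.components["EX_a__rev"].upper_bound == 10.0

    def test_unlisted_uptake_closed_secretion_open(self):
        net, _, _ = two_route_network()
        constrained = apply_media(split_reversible(net), MediaCondition("empty", {}))
        assert constrained.components["EX_a__rev"].upper_bound == 0.0
        assert constrained.components["EX_a__fwd"].upper_bound == 1000.0

    def test_empty_media_starves_biomass(self):
        net, _, _ = two_route_network()
        assert fba_growth(net, MediaCondition("empty", {})) == 0.0

    def test_internal_reaction_in_media_rejected(self):
        net, _, _ = two_route_network()
        with pytest.raises(MediaError, match="non-exchange"):
            apply_media(split_reversible(net), MediaCondition("bad", {"P": 5.0}))

    def test_internal_bounds_never_altered(self):
        net, media, _ = two_route_network()
        split = split_reversible(net)
        constrained = apply_media(split, media)
        for cid, comp in constrained.components.items():
            if split.base.reactions[comp.base_id].kind != "exchange":
                assert comp.upper_bound == split.components[cid].upper_bound
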