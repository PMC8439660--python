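"""Network construction: counts, conservation, symbol maps, SBML round trip."""

import numpy as np
import pytest

from symphos.networks import (
    ConfigurationError,
    NetworkSpec,
    ParameterSet,
    RateTriplet,
    Totals,
    build_network,
    catalogue,
    symbol_map,
)
from symphos.paramgen import sample_params
from symphos.sbml import export_sbml, parse_sbml

# hand enumeration: every modification arrow expands to bind/unbind/catalyse,
# processive channels to bind/unbind/two catalytic steps with two complexes
EXPECTED_COUNTS = {
    #                 species, reactions, conservation laws
    "random_ckcp": (14, 24, 3),
    "random_skcp": (15, 24, 4),
    "random_sksp": (16, 24, 5),
    "ordered_ckcp": (9, 12, 3),
    "ordered_sksp": (11, 12, 5),
    "mixed1": (14, 20, 3),
    "mixed2": (15, 20, 4),
    "ordered_tsp": (12, 18, 3),
    "single_site": (6, 6, 3),
    "square": (20, 24, 9),
}


@pytest.mark.parametrize("name", sorted(EXPECTED_COUNTS))
def test_catalogue_counts(name):
    net = build_network(catalogue()[name])
    assert (net.n_species, net.n_reactions, net.n_conservation_laws) == EXPECTED_COUNTS[name]


@pytest.mark.parametrize("name", sorted(EXPECTED_COUNTS))
def test_conservation_vectors_are_exact_left_null_vectors(name):
    net = build_network(catalogue()[name])
    for v in net.conservation_basis.values():
        assert np.all(v @ net.stoich_matrix == 0)
    # complexes participate in formation and consumption
    for c in net.complexes:
        assert np.count_nonzero(net.stoich_matrix[net.species_index[c]]) >= 2
    # substrate law covers every substrate form and complex exactly once
    v = net.conservation_basis["substrate"]
    assert sum(v) == len(net.substrate_forms) + len(net.complexes)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(topology="random_dsp", phosphatase_mode="separate", dephosphorylation="processive"),
        dict(topology="ordered_dsp", dephosphorylation="processive"),
        dict(topology="ordered_tsp", kinase_mode="separate"),
        dict(topology="square", kinase_mode="common"),
    ],
)
def test_invalid_spec_combinations_raise(kwargs):
    with pytest.raises(ConfigurationError):
        NetworkSpec(**kwargs)


def test_rate_triplet_positivity():
    with pytest.raises(ConfigurationError):
        RateTriplet(1.0, -1.0, 1.0)
    with pytest.raises(ConfigurationError):
        RateTriplet(0.0, 1.0, 1.0)


def test_symbol_map_targets_catalytic_constants():
    spec = catalogue()["random_ckcp"]
    m = symbol_map(spec)
    assert m["k1"] == ("p:A00>A01", "cat")
    assert m["k2"] == ("p:A01>A11", "cat")
    assert m["a1"] == ("p:A00>A10", "cat")
    assert m["k3"] == ("d:A11>A01", "cat")
    assert m["k4"] == ("d:A01>A00", "cat")
    assert symbol_map(catalogue()["ordered_ckcp"])["k2"] == ("p:Ap>App", "cat")


def test_parameter_validation_names_mismatched_arrows():
    net = build_network(catalogue()["ordered_ckcp"])
    triplets = {a: RateTriplet(1, 1, 1) for a in net.arrows}
    triplets["p:A00>A11"] = triplets.pop("p:A>Ap")
    p = ParameterSet(triplets, Totals(1.0, {"K": 1.0, "P": 1.0}))
    with pytest.raises(ConfigurationError, match="p:A00>A11"):
        p.validate_for(net)


@pytest.mark.parametrize("name", ["ordered_ckcp", "mixed2", "single_site"])
def test_sbml_round_trip_preserves_stoichiometry_and_rates(name):
    spec = catalogue()[name]
    net = build_network(spec)
    params = sample_params(spec, 5)
    doc = export_sbml(net, params)
    parsed = parse_sbml(doc)
    assert len(parsed.species) == net.n_species
    assert np.array_equal(parsed.stoich_matrix(), net.stoich_matrix)
    assert np.allclose(parsed.rate_constants(), net.rate_constants(params), rtol=0)


def test_sbml_rejects_mismatched_params():
    spec = catalogue()["ordered_ckcp"]
    net = build_network(spec)
    wrong = sample_params(catalogue()["random_ckcp"], 0)
    with pytest.raises(ConfigurationError):
        export_sbml(net, wrong)
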