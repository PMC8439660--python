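"""Mass-action RHS/Jacobian, reduction, integration, oscillation diagnostics."""

import numpy as np
import pytest

from symphos.dynamics import (
    Reduction,
    Trajectory,
    detect_oscillations,
    jacobian,
    reduce,
    rhs,
    simulate,
)
from symphos.networks import ParameterSet, RateTriplet, Totals, build_network, catalogue
from symphos.paramgen import sample_params, sample_symmetric
from symphos.symmetry import involution_for, state_residual


def single_site_params(k_on=2.0):
    net = build_network(catalogue()["single_site"])
    tr = {a: RateTriplet(k_on, 1.0, 1.0) for a in net.arrows}
    return net, ParameterSet(tr, Totals(1.0, {"K": 1.0, "P": 1.0}))


def test_rhs_elementary_term_by_hand():
    net, p = single_site_params(k_on=2.0)
    x = np.zeros(net.n_species)
    x[net.species_index["A"]] = 1.0
    x[net.species_index["K"]] = 1.0
    d = rhs(net, p, x)
    assert d[net.species_index["K.p:A>Ap"]] == pytest.approx(2.0)
    assert d[net.species_index["A"]] == pytest.approx(-2.0)
    assert rhs(net, p, np.zeros(net.n_species)) == pytest.approx(0.0)


@pytest.mark.parametrize("name", ["random_ckcp", "mixed2", "ordered_tsp", "square"])
def test_rhs_orthogonal_to_conservation_vectors(name):
    spec = catalogue()[name]
    net = build_network(spec)
    p = sample_params(spec, 1)
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = rng.uniform(0.0, 2.0, net.n_species)
        d = rhs(net, p, x)
        for v in net.conservation_basis.values():
            assert abs(v @ d) <= 1e-13 * max(1.0, np.max(np.abs(d)))


@pytest.mark.parametrize("name", ["random_sksp", "mixed1", "ordered_ckcp"])
def test_jacobian_matches_central_differences(name):
    spec = catalogue()[name]
    net = build_network(spec)
    p = sample_params(spec, 3)
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = rng.uniform(0.1, 1.0, net.n_species)
        J = jacobian(net, p, x)
        h = 1e-6
        for j in rng.choice(net.n_species, size=4, replace=False):
            e = np.zeros(net.n_species)
            e[j] = h
            col = (rhs(net, p, x + e) - rhs(net, p, x - e)) / (2 * h)
            assert np.allclose(J[:, j], col, rtol=1e-6, atol=1e-8 * np.max(np.abs(J)))


def test_jacobian_columns_sum_to_zero_against_conservation():
    spec = catalogue()["random_ckcp"]
    net = build_network(spec)
    p = sample_params(spec, 7)
    x = np.random.default_rng(0).uniform(0.1, 1.0, net.n_species)
    J = jacobian(net, p, x)
    for v in net.conservation_basis.values():
        assert np.allclose(v @ J, 0.0, atol=1e-12 * np.max(np.abs(J)))


@pytest.mark.parametrize(
    "name,n_red", [("random_ckcp", 11), ("single_site", 3), ("random_sksp", 11)]
)
def test_reduction_dimensions_and_lift_inverse(name, n_red):
    spec = catalogue()[name]
    net = build_network(spec)
    red = reduce(net)
    assert red.n_reduced == net.n_species - net.n_conservation_laws == n_red
    p = sample_params(spec, 9)
    rng = np.random.default_rng(1)
    y = rng.uniform(0.01, 0.2, red.n_reduced)
    x = red.lift(y, p.totals)
    assert np.allclose(red.reduce_state(x), y)
    # lifted state satisfies every conservation law exactly
    assert net.conservation_basis["substrate"] @ x == pytest.approx(
        p.totals.substrate_total
    )
    for e in net.enzymes:
        assert net.conservation_basis[e] @ x == pytest.approx(
            p.totals.enzyme_totals[e]
        )


def test_simulation_conserves_totals_and_symmetry():
    spec = catalogue()["random_ckcp"]
    inv = involution_for(spec, "case2")
    net = inv.network
    p = sample_symmetric(spec, "case2", 3)
    x0 = np.zeros(net.n_species)
    w = p.totals.substrate_total / 4
    for s in net.substrate_forms:
        x0[net.species_index[s]] = w
    for e in net.enzymes:
        x0[net.species_index[e]] = p.totals.enzyme_totals[e]
    traj = simulate(net, p, x0, 50.0, rtol=1e-9)
    sub = traj.states @ net.conservation_basis["substrate"]
    assert np.allclose(sub, p.totals.substrate_total, rtol=1e-10)
    assert max(state_residual(x, inv) for x in traj.states) <= 1e-8
    assert traj.states.min() >= -1e-9 * p.totals.substrate_total


def _sine_trajectory(period, n=4000, t_end=200.0):
    net = build_network(catalogue()["single_site"])
    t = np.linspace(0, t_end, n)
    X = np.ones((n, net.n_species))
    X[:, 0] = 2.0 + np.sin(2 * np.pi * t / period)
    return Trajectory(net, t, X, True)


def test_detect_oscillations_recovers_period_of_synthetic_signal():
    rep = detect_oscillations(_sine_trajectory(7.0))
    assert rep.sustained and rep.conclusive
    assert rep.period == pytest.approx(7.0, rel=0.02)


def test_detect_oscillations_flags_convergence_and_short_tails():
    net = build_network(catalogue()["single_site"])
    t = np.linspace(0, 40, 500)
    X = np.ones((500, net.n_species)) * 0.5
    X[:, 0] = 1.0 + np.exp(-t)  # decays to steady state
    rep = detect_oscillations(Trajectory(net, t, X, True))
    assert not rep.sustained and rep.conclusive
    short = detect_oscillations(_sine_trajectory(90.0, n=300, t_end=200.0))
    assert not short.conclusive
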