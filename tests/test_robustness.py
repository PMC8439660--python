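"""Concentration-robustness measurements, invariant discovery, limiting regimes."""

import numpy as np
import pytest

from symphos.networks import build_network, catalogue
from symphos.paramgen import perturb_symmetry, sample_params
from symphos.robustness import (
    acr_deviation,
    approx_acr_params,
    discover_invariants,
    transcritical_acr_scan,
)
from symphos.symmetry import involution_for


def test_partial_form_pinned_on_asymmetric_branches(run_switched):
    inv, pf, b1, b2 = run_switched("ordered_case1")
    for br in (b1, b2):
        rec = acr_deviation(br, "Ap", reference=pf.x[inv.network.species_index["Ap"]])
        assert rec.max_rel_deviation <= 1e-6
        assert rec.reference == pytest.approx(3.0, rel=1e-6)


def test_symmetric_branch_has_no_partial_form_robustness(run_fixture):
    inv, rep = run_fixture("ordered_case1")
    pre = [p for p in rep.branch.points if p.a_total < 12.0]
    from symphos.continuation import Branch

    sub = Branch(rep.branch.network, rep.branch.params, pre)
    rec = acr_deviation(sub, "Ap")
    assert rec.max_rel_deviation > 1e-2  # Ap tracks A_Total before breaking


@pytest.mark.parametrize(
    "fixture,expected",
    [
        ("random_ckcp_case1", {"A01", "A10"}),
        ("sksp_case2", {"A00", "A11"}),
    ],
)
def test_discovered_individual_invariants_match_network_and_case(
    run_switched, fixture, expected
):
    inv, pf, b1, b2 = run_switched(fixture)
    found = discover_invariants([b1, b2], tol=1e-6)
    singles = {t for t, hits, _ in found if isinstance(t, str) and len(hits) == 2}
    assert singles == expected


def test_case3_discovers_only_the_pair_sum(run_switched):
    inv, pf, b1, b2 = run_switched("case3_ckcp_super")
    found = discover_invariants([b1, b2], tol=1e-6)
    singles = {t for t, _, _ in found if isinstance(t, str)}
    pairs = {t for t, _, _ in found if not isinstance(t, str)}
    assert singles == set()
    assert pairs == {("A01", "A10")}


def test_case3_sksp_invariant_is_only_approximate(run_switched):
    inv, pf, b1, b2 = run_switched("case3_sksp_super")
    found = discover_invariants([b1, b2], tol=1e-6)
    assert found == []  # no exact invariant at 1e-6
    devs = {
        t: max(acr_deviation(b1, t).max_rel_deviation,
               acr_deviation(b2, t).max_rel_deviation)
        for t in (("A01", "A10"), ("A00", "A11"))
    }
    assert min(devs.values()) < 0.15  # one sum is approximately constant
    assert min(devs.values()) > 1e-6  # but not exactly


def test_transcritical_scan_on_nonsymmetric_acr_fixture(lib):
    fx = lib["ordered_acr_nonsym"]
    net = build_network(fx.spec)
    rep = transcritical_acr_scan(net, fx.params, fx.a_range, seed=0)
    acr_levels = [v for v, f in zip(rep.acr_values, rep.acr_flags) if f]
    assert len(acr_levels) >= 2
    assert np.allclose(acr_levels, 2.662993572084481, rtol=1e-6)
    assert any(not f for f in rep.acr_flags)  # a non-robust branch coexists
    assert any(ev["kind"] == "transcritical" for ev in rep.intersections)
    assert rep.robust_vs_enzyme_totals is False


def test_symmetric_scan_reports_pitchfork_crossing(lib):
    fx = lib["ordered_case1"]
    inv = involution_for(fx.spec, "case1")
    net = build_network(fx.spec)
    rep = transcritical_acr_scan(net, fx.params, (0.5, 30.0), seed=0, involution=inv)
    acr_levels = [v for v, f in zip(rep.acr_values, rep.acr_flags) if f]
    assert len(acr_levels) >= 2 and np.allclose(acr_levels, 3.0, rtol=1e-6)
    assert any(ev["kind"] == "pitchfork" for ev in rep.intersections)


@pytest.mark.parametrize("target", ["App", "Ap", "A"])
def test_limiting_regime_gives_approximate_acr_without_multistability(target):
    spec = catalogue()["ordered_ckcp"]
    params, dev, reached = approx_acr_params(spec, target, seed=1)
    assert reached
    assert dev < 0.05


def test_generic_parameters_are_a_negative_control_for_approx_acr():
    """Without the regime construction the fully modified form tracks A_Total."""
    spec = catalogue()["ordered_ckcp"]
    net = build_network(spec)
    p = sample_params(spec, 8)
    from symphos.steady import sweep_steady_states

    vals = []
    for a in np.geomspace(10.0, 20.0, 6):
        pp = p.replace_totals(p.totals.with_substrate(float(a)))
        sols = sweep_steady_states(net, pp, n_starts=4, seed=0)
        vals.append(sols[0].x[net.species_index["App"]])
    dev = np.max(np.abs(np.array(vals) - vals[0])) / vals[0]
    assert dev > 0.05


def test_imperfect_symmetry_unfolds_pitchfork_monotonically(lib):
    """Perturbing the rate symmetry by eps disconnects the pitchfork; the
    deviation of the former invariant shrinks as eps -> 0."""
    fx = lib["ordered_case1"]
    inv = involution_for(fx.spec, "case1")
    net = inv.network
    from symphos.continuation import ContinuationOptions, continue_branch
    from symphos.steady import solve_steady

    # small steps: the connected branch must track the narrow avoided crossing
    # left by the unfolded pitchfork instead of jumping across it
    opts = ContinuationOptions(ds0_rel=1e-3, ds_max_rel=2e-3)
    devs = []
    for eps in (1e-2, 1e-3, 1e-4):
        p = perturb_symmetry(fx.params, inv, eps, seed=2)
        p0 = p.replace_totals(p.totals.with_substrate(0.5))
        x0 = np.zeros(net.n_species)
        x0[net.species_index["A"]] = 0.5
        for e in net.enzymes:
            x0[net.species_index[e]] = p0.totals.enzyme_totals[e]
        res = solve_steady(net, p0, x0)
        br = continue_branch(net, p0, (0.5, 30.0), res.x, involution=inv,
                             enforce_symmetry=False, options=opts)
        # connected: no pitchfork on the path, yet it ends strongly asymmetric
        assert not [b for b in br.bifurcations if b.kind == "pitchfork"]
        assert br.max_state_residual() > 1e-4
        ap = br.species_values("Ap")
        sel = br.a_values > 15.0  # well past the former bifurcation
        devs.append(float(np.max(np.abs(ap[sel] - 3.0)) / 3.0))
    assert devs[0] > devs[1] > devs[2]
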