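"""Continuation, bifurcation detection, branch switching, classification."""

import numpy as np
import pytest

from symphos.continuation import classify_pitchfork, continue_branch
from symphos.networks import build_network, catalogue
from symphos.paramgen import sample_params
from symphos.steady import solve_steady, sweep_steady_states
from symphos.symmetry import involution_for, state_residual


def test_single_site_branch_is_smooth_and_bifurcation_free():
    spec = catalogue()["single_site"]
    net = build_network(spec)
    p = sample_params(spec, 4)
    p = p.replace_totals(p.totals.with_substrate(0.1))
    x0 = np.zeros(net.n_species)
    x0[net.species_index["A"]] = 0.1
    for e in net.enzymes:
        x0[net.species_index[e]] = p.totals.enzyme_totals[e]
    res = solve_steady(net, p, x0)
    br = continue_branch(net, p, (0.1, 20.0), res.x)
    assert not br.truncated
    assert br.bifurcations == []
    assert all(pt.stability == "stable" for pt in br.points)
    a = br.a_values
    assert a[0] == pytest.approx(0.1) and a[-1] == pytest.approx(20.0)
    assert np.all(np.diff(a) > 0)


def test_every_branch_point_is_a_steady_state(run_fixture):
    inv, rep = run_fixture("ordered_case1")
    from symphos.dynamics import ReducedSystem

    base = ReducedSystem(inv.network, rep.branch.params)
    for pt in rep.branch.points[::3]:
        sys = base.with_substrate(pt.a_total)
        assert np.max(np.abs(sys.f(pt.y))) <= 1e-9 * sys.rate_scale()


def test_ordered_fixture_has_exactly_one_supercritical_pitchfork(run_fixture, run_switched):
    inv, rep = run_fixture("ordered_case1")
    assert rep.branch.is_symmetric
    pfs = [b for b in rep.branch.bifurcations if b.kind == "pitchfork"]
    assert len(pfs) == 1
    assert pfs[0].a_total == pytest.approx(12.5, rel=1e-6)
    _, pf, b1, b2 = run_switched("ordered_case1")
    assert classify_pitchfork(pf, (b1, b2), rep.branch) == "supercritical"


def test_switched_branches_are_asymmetric_sigma_images(run_switched):
    inv, pf, b1, b2 = run_switched("ordered_case1")
    net = inv.network
    assert b1.max_state_residual() > 1e-3
    params = b1.params
    n = 0
    for pt in b1.points[:: max(1, len(b1.points) // 10)]:
        a2 = b2.a_values
        j = int(np.argmin(np.abs(a2 - pt.a_total)))
        p = params.replace_totals(params.totals.with_substrate(pt.a_total))
        # re-solve the mirror branch at exactly this A_Total from its nearest
        # recorded point and compare with the sigma image point-by-point
        res = solve_steady(net, p, b2.points[j].x)
        if not res.converged:
            continue
        assert np.max(np.abs(inv.apply(pt.x) - res.x)) <= 1e-8 * max(pt.a_total, 1.0)
        n += 1
    assert n >= 5  # the two directions give genuinely matched mirror branches


def test_branch_points_match_multistart_sweep(run_fixture):
    inv, rep = run_fixture("ordered_case1")
    net = inv.network
    pts = rep.branch.points[:: max(1, len(rep.branch.points) // 8)]
    for pt in pts:
        p = rep.branch.params.replace_totals(
            rep.branch.params.totals.with_substrate(pt.a_total)
        )
        sols = sweep_steady_states(net, p, n_starts=8, seed=5)
        conc = max(pt.a_total, 1.0)
        assert any(np.max(np.abs(s.x - pt.x)) <= 1e-6 * conc for s in sols)


def test_subcritical_fixture_pitchfork_and_folds(run_fixture, run_switched):
    inv, rep = run_fixture("case3_ckcp_subcritical")
    pfs = [b for b in rep.branch.bifurcations if b.kind == "pitchfork"]
    assert len(pfs) == 1
    _, pf, b1, b2 = run_switched("case3_ckcp_subcritical")
    assert classify_pitchfork(pf, (b1, b2), rep.branch) == "subcritical"
    folds = [b for br in (b1, b2) for b in br.bifurcations if b.kind == "fold"]
    assert len(folds) == 2
    for f in folds:
        assert f.a_total < pf.a_total  # the branches bend backwards first


def test_hopf_detected_before_pitchfork_on_oscillatory_fixture(run_fixture):
    inv, rep = run_fixture("case3_ckcp_hopf")
    kinds = [(b.kind, b.a_total) for b in rep.branch.bifurcations]
    hopfs = [a for k, a in kinds if k == "hopf"]
    pfs = [a for k, a in kinds if k == "pitchfork"]
    assert hopfs and pfs
    assert min(hopfs) < min(pfs)
    hp = [b for b in rep.branch.bifurcations if b.kind == "hopf"][0]
    assert abs(hp.eigenvalue.imag) > 0  # genuine complex pair on the axis


def test_case3_asymmetric_branches_break_both_symmetries_together(run_switched):
    """On every asymmetric branch of the diagonal symmetry, |A00 - A11| and
    |A01 - A10| exceed tolerance together."""
    inv, pf, b1, b2 = run_switched("case3_ckcp_super")
    net = inv.network
    i = net.species_index
    for br in (b1, b2):
        for pt in br.points:
            if state_residual(pt.x, inv) > 1e-3:
                scale = pt.a_total
                assert abs(pt.x[i["A00"]] - pt.x[i["A11"]]) > 1e-5 * scale
                assert abs(pt.x[i["A01"]] - pt.x[i["A10"]]) > 1e-5 * scale
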