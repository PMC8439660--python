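"""Analytic breaking criteria: sign logic, contracts, numeric concordance."""

import numpy as np
import pytest

from symphos.criteria import (
    CriterionConstants,
    MissingConstantError,
    criterion_ordered_ckcp_case1,
    criterion_random_ckcp_case1,
    criterion_random_ckcp_case3,
    criterion_random_sksp_case1,
    criterion_random_sksp_case2,
    numeric_breaking_test,
)
from symphos.networks import ParameterSet, RateTriplet, Totals, build_network, catalogue, symbol_map
from symphos.paramgen import _rescale_kcat_pair, sample_params, sample_symmetric
from symphos.symmetry import involution_for, symmetrize


def _set_kcat(params, spec, symbol, value, case):
    inv = involution_for(spec, case)
    arrow = symbol_map(spec)[symbol][0]
    return _rescale_kcat_pair(params, inv, arrow, value / params.triplets[arrow].k_cat)


def test_ordered_criterion_is_strict_inequality_in_k2_k1():
    spec = catalogue()["ordered_ckcp"]
    p = sample_symmetric(spec, "case1", 0)
    p = _set_kcat(p, spec, "k1", 1.0, "case1")
    for k2, expect in [(2.0, True), (1.0, False), (0.5, False)]:
        q = _set_kcat(p, spec, "k2", k2, "case1")
        assert criterion_ordered_ckcp_case1(spec, q) is expect


def test_criteria_reject_asymmetric_parameters():
    spec = catalogue()["ordered_ckcp"]
    p = sample_params(spec, 1)  # not symmetrized
    with pytest.raises(ValueError, match="symmetr"):
        criterion_ordered_ckcp_case1(spec, p)


def test_random_ckcp_case1_sign_logic():
    spec = catalogue()["random_ckcp"]
    base = sample_symmetric(spec, "case1", 2)
    both_up = _set_kcat(_set_kcat(base, spec, "k1", 1.0, "case1"), spec, "a1", 1.0, "case1")
    both_up = _set_kcat(_set_kcat(both_up, spec, "k2", 3.0, "case1"), spec, "a2", 2.0, "case1")
    assert criterion_random_ckcp_case1(spec, both_up) > 0
    both_dn = _set_kcat(_set_kcat(base, spec, "k2", 1.0, "case1"), spec, "a2", 1.0, "case1")
    both_dn = _set_kcat(_set_kcat(both_dn, spec, "k1", 3.0, "case1"), spec, "a1", 2.0, "case1")
    assert criterion_random_ckcp_case1(spec, both_dn) < 0
    mixed = _set_kcat(_set_kcat(base, spec, "k1", 1.0, "case1"), spec, "k2", 3.0, "case1")
    mixed = _set_kcat(_set_kcat(mixed, spec, "a1", 2.0, "case1"), spec, "a2", 1.0, "case1")
    with pytest.raises(MissingConstantError):
        criterion_random_ckcp_case1(spec, mixed)
    assert criterion_random_ckcp_case1(spec, mixed, CriterionConstants(alpha=0.01)) > 0
    assert criterion_random_ckcp_case1(spec, mixed, CriterionConstants(alpha=10.0)) < 0


def test_sksp_case1_criterion_window_on_totals():
    spec = catalogue()["random_sksp"]
    p = sample_symmetric(spec, "case1", 3)
    et = dict(p.totals.enzyme_totals)
    # equal phosphatase totals: criterion reduces to k2>k1 and a2>a1
    for e in et:
        et[e] = 1.0
    p = ParameterSet(dict(p.triplets), Totals(p.totals.substrate_total, et))
    p = _set_kcat(_set_kcat(p, spec, "k1", 1.0, "case1"), spec, "k2", 2.0, "case1")
    p = _set_kcat(_set_kcat(p, spec, "a1", 1.0, "case1"), spec, "a2", 2.0, "case1")
    assert criterion_random_sksp_case1(spec, p) is True
    # ratio of phosphatase totals outside both k-ratio windows -> False
    et2 = dict(et)
    et2["P2"] = et2["K1"] = 3.0  # P2/P1 = 3 > k2/k1; pairing keeps symmetry
    q = ParameterSet(dict(p.triplets), Totals(p.totals.substrate_total, et2))
    assert criterion_random_sksp_case1(spec, q) is False


def test_sksp_case2_criterion_window_logic():
    spec = catalogue()["random_sksp"]
    p = sample_symmetric(spec, "case2", 4)
    et = {e: 1.0 for e in p.totals.enzyme_totals}  # PT/KT = 1
    p = ParameterSet(dict(p.triplets), Totals(p.totals.substrate_total, et))
    # k1/k4 = 2 > 1 > k2/k3 = 0.5 -> breaking possible
    p = _set_kcat(_set_kcat(p, spec, "k1", 2.0, "case2"), spec, "k4", 1.0, "case2")
    p = _set_kcat(_set_kcat(p, spec, "k2", 1.0, "case2"), spec, "k3", 2.0, "case2")
    assert criterion_random_sksp_case2(spec, p) is True
    # k1/k4 < k2/k3 precludes it for every totals ratio
    q = _set_kcat(_set_kcat(p, spec, "k1", 0.5, "case2"), spec, "k2", 4.0, "case2")
    assert criterion_random_sksp_case2(spec, q) is False


def test_case3_criterion_sign_logic():
    spec = catalogue()["random_ckcp"]
    base = sample_symmetric(spec, "case3", 5)
    ok = _set_kcat(_set_kcat(base, spec, "k2", 2.0, "case3"), spec, "k3", 1.0, "case3")
    ok = _set_kcat(_set_kcat(ok, spec, "k4", 2.0, "case3"), spec, "k1", 1.0, "case3")
    assert criterion_random_ckcp_case3(spec, ok) > 0
    bad = _set_kcat(_set_kcat(base, spec, "k2", 1.0, "case3"), spec, "k3", 2.0, "case3")
    bad = _set_kcat(_set_kcat(bad, spec, "k4", 1.0, "case3"), spec, "k1", 2.0, "case3")
    assert criterion_random_ckcp_case3(spec, bad) < 0
    mixed = _set_kcat(_set_kcat(base, spec, "k2", 1.0, "case3"), spec, "k3", 2.0, "case3")
    mixed = _set_kcat(_set_kcat(mixed, spec, "k4", 2.0, "case3"), spec, "k1", 1.0, "case3")
    with pytest.raises(MissingConstantError):
        criterion_random_ckcp_case3(spec, mixed)
    assert criterion_random_ckcp_case3(spec, mixed, CriterionConstants(c1=10, c3=0.1)) > 0


@pytest.mark.parametrize("cond,expect", [("satisfy", True), ("violate", False)])
def test_numeric_oracle_agrees_with_ordered_criterion(cond, expect):
    spec = catalogue()["ordered_ckcp"]
    for seed in range(4):
        p = sample_symmetric(spec, "case1", seed, cond)
        assert criterion_ordered_ckcp_case1(spec, p) is expect
        rep = numeric_breaking_test(spec, p, case="case1")
        assert rep.broken is expect


def test_numeric_test_rejects_asymmetric_parameters():
    spec = catalogue()["ordered_ckcp"]
    with pytest.raises(ValueError):
        numeric_breaking_test(spec, sample_params(spec, 0), case="case1")
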