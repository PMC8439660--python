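import numpy as np
import pytest

from symphos.continuation import switch_branch
from symphos.criteria import numeric_breaking_test
from symphos.networks import catalogue
from symphos.paramgen import regime_library
from symphos.symmetry import involution_for


@pytest.fixture(scope="session")
def cat():
    return catalogue()


@pytest.fixture(scope="session")
def lib():
    return regime_library()


@pytest.fixture(scope="session")
def branch_cache():
    """Session-wide cache of expensive continuation results, keyed by fixture
    name, so independent tests can share one symmetric-branch run."""
    return {}


@pytest.fixture(scope="session")
def run_fixture(lib, branch_cache):
    """Continue a fixture's symmetric branch (cached) and return the report."""

    def _run(name):
        if name not in branch_cache:
            fx = lib[name]
            inv = involution_for(fx.spec, fx.case)
            branch_cache[name] = (
                inv,
                numeric_breaking_test(fx.spec, fx.params, inv=inv, a_range=fx.a_range),
            )
        return branch_cache[name]

    return _run


@pytest.fixture(scope="session")
def run_switched(lib, run_fixture, branch_cache):
    """Both asymmetric branches emanating from a fixture's first pitchfork."""

    def _run(name):
        key = name + "/switched"
        if key not in branch_cache:
            fx = lib[name]
            inv, rep = run_fixture(name)
            pf = [b for b in rep.branch.bifurcations if b.kind == "pitchfork"][0]
            net = inv.network
            b1 = switch_branch(net, fx.params, pf, +1, fx.a_range, inv)
            b2 = switch_branch(net, fx.params, pf, -1, fx.a_range, inv)
            branch_cache[key] = (inv, pf, b1, b2)
        return branch_cache[key]

    return _run
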