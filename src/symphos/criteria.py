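"""Analytic conditions for symmetry breaking, with a numerical existence test.

Each criterion takes a *symmetric* parameter set (contract-checked) and
expresses the published inequality in the catalytic constants (and, where
relevant, total enzyme concentrations):

* ordered, common K/P, Case 1:        ``k2 > k1``
* random, common K/P, Case 1:         ``(k2 - k1) + alpha (k2/a2)(a2 - a1) > 0``
* random, separate K/P, Case 1:       ``k2/k1 > P1T/P2T`` and ``a2/a1 > P2T/P1T``
* random, separate K/P, Case 2:       ``k1/k4 > PT/KT > k2/k3``
* random, common K/P, Case 3:         ``c3 (1 - k3/k2) + c1 (1 - k1/k4) > 0``

``alpha``, ``c1``, ``c3`` are positive constants determined by the remaining
kinetic parameters; their closed forms are not transcribed here, so the signed
criteria are only evaluated when their sign does not depend on them (both
terms agreeing), and otherwise defer to :func:`numeric_breaking_test`, the
ground-truth oracle that continues the symmetric branch and watches the
antisymmetric test function.

All inequalities are strict: equality is the degenerate boundary and is
reported as non-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuation import Branch, ContinuationOptions, continue_branch
from .networks import (
    ConfigurationError,
    EnzymeMode,
    NetworkSpec,
    ParameterSet,
    ReactionNetwork,
    Topology,
    build_network,
    symbol_map,
)
from .steady import solve_steady
from .symmetry import Involution, involution_for, symmetry_residual

__all__ = [
    "CriterionConstants",
    "MissingConstantError",
    "criterion_ordered_ckcp_case1",
    "criterion_random_ckcp_case1",
    "criterion_random_sksp_case1",
    "criterion_random_sksp_case2",
    "criterion_random_ckcp_case3",
    "numeric_breaking_test",
    "BreakingReport",
    "DEFAULT_SCAN_FACTOR",
]

#: default A_Total scan cap for "breaking exists for *some* total substrate":
#: multiple of the largest enzyme total (configurable per call).
DEFAULT_SCAN_FACTOR = 1e3

_SYM_CONTRACT = 1e-9


@dataclass(frozen=True)
class CriterionConstants:
    """Positive constants of the signed criteria (functions of the kinetics)."""

    alpha: float | None = None
    c1: float | None = None
    c3: float | None = None

    def __post_init__(self):
        for name in ("alpha", "c1", "c3"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigurationError(f"{name} must be positive, got {v!r}")


class MissingConstantError(ConfigurationError):
    """Criterion sign depends on an unavailable constant."""


def _check(spec: NetworkSpec, params: ParameterSet, case: str) -> dict[str, float]:
    inv = involution_for(spec, case)
    r = symmetry_residual(params, inv)
    if r > _SYM_CONTRACT:
        raise ValueError(
            f"criterion requires {case}-symmetric parameters "
            f"(symmetry residual {r:.3g} > {_SYM_CONTRACT})"
        )
    sym = symbol_map(spec)
    return {s: params.triplets[a].k_cat for s, (a, _) in sym.items()}


def criterion_ordered_ckcp_case1(spec: NetworkSpec, params: ParameterSet) -> bool:
    """Breaking of the modification-direction symmetry in the ordered chain
    is possible (and guaranteed for some A_Total) iff the second
    phosphorylation outpaces the first: k2 > k1."""
    if spec.topology is not Topology.ordered_dsp or spec.kinase_mode is not EnzymeMode.common:
        raise ConfigurationError("criterion applies to the ordered common-K/common-P network")
    k = _check(spec, params, "case1")
    return k["k2"] > k["k1"]


def criterion_random_ckcp_case1(
    spec: NetworkSpec,
    params: ParameterSet,
    consts: CriterionConstants | None = None,
) -> float:
    """Signed criterion (k2 - k1) + alpha (k2/a2)(a2 - a1); positive means an
    asymmetric state exists for some A_Total."""
    if spec.topology is not Topology.random_dsp or spec.kinase_mode is not EnzymeMode.common:
        raise ConfigurationError("criterion applies to the random common-K/common-P network")
    k = _check(spec, params, "case1")
    alpha = consts.alpha if consts else None
    t1, t2 = k["k2"] - k["k1"], (k["k2"] / k["a2"]) * (k["a2"] - k["a1"])
    if alpha is None:
        if t1 * t2 >= 0:
            alpha = 1.0  # sign does not depend on alpha
        else:
            raise MissingConstantError(
                "the sign of the criterion depends on alpha, which was not "
                "supplied; resolve with numeric_breaking_test"
            )
    return t1 + alpha * t2


def criterion_random_sksp_case1(spec: NetworkSpec, params: ParameterSet) -> bool:
    """Both-leg condition with enzyme totals: on the leg through A01,
    k2/k1 > P1T/P2T, and on the leg through A10, a2/a1 > P2T/P1T (strict).

    Under the package's site convention (Ki phosphorylates site i, Pi
    dephosphorylates site i; Case 1 pairs K1 with P2 and K2 with P1) the
    phosphatase completing the first leg's final dephosphorylation carries
    index 2; the inequality orientation was confirmed against the numeric
    oracle on seeded symmetric ensembles (no false positives or negatives).
    """
    if spec.topology is not Topology.random_dsp or spec.kinase_mode is not EnzymeMode.separate \
            or spec.phosphatase_mode is not EnzymeMode.separate:
        raise ConfigurationError("criterion applies to the random separate-K/separate-P network")
    k = _check(spec, params, "case1")
    et = params.totals.enzyme_totals
    r = et["P1"] / et["P2"]
    return k["k2"] / k["k1"] > r and k["a2"] / k["a1"] > 1.0 / r


def criterion_random_sksp_case2(spec: NetworkSpec, params: ParameterSet) -> bool:
    """Leg-exchange symmetry can break iff the totals ratio lies strictly in
    the window: k1/k4 > PT/KT > k2/k3."""
    if spec.topology is not Topology.random_dsp or spec.kinase_mode is not EnzymeMode.separate \
            or spec.phosphatase_mode is not EnzymeMode.separate:
        raise ConfigurationError("criterion applies to the random separate-K/separate-P network")
    k = _check(spec, params, "case2")
    et = params.totals.enzyme_totals
    ratio = et["P1"] / et["K1"]  # PT/KT; pairs are equal under case2 symmetry
    return k["k1"] / k["k4"] > ratio and k["k2"] / k["k3"] < ratio


def criterion_random_ckcp_case3(
    spec: NetworkSpec,
    params: ParameterSet,
    consts: CriterionConstants | None = None,
) -> float:
    """Signed criterion c3 (1 - k3/k2) + c1 (1 - k1/k4); positive means an
    asymmetric state is possible (and realized for some A_Total)."""
    if spec.topology is not Topology.random_dsp or spec.kinase_mode is not EnzymeMode.common:
        raise ConfigurationError("criterion applies to the random common-K/common-P network")
    k = _check(spec, params, "case3")
    t3, t1 = 1.0 - k["k3"] / k["k2"], 1.0 - k["k1"] / k["k4"]
    c1 = consts.c1 if consts else None
    c3 = consts.c3 if consts else None
    if c1 is None or c3 is None:
        if t1 * t3 >= 0:
            c1 = c3 = 1.0
        else:
            raise MissingConstantError(
                "the sign of the criterion depends on c1/c3, which were not "
                "supplied; resolve with numeric_breaking_test"
            )
    return c3 * t3 + c1 * t1


# ---------------------------------------------------------------------------
# numerical ground truth


@dataclass
class BreakingReport:
    broken: bool
    pitchfork_a_total: float | None
    branch: Branch
    partial: bool  # branch truncated before the scan cap
    message: str = ""


def _symmetric_start(network: ReactionNetwork, params: ParameterSet) -> np.ndarray:
    x = np.zeros(network.n_species)
    w = params.totals.substrate_total / len(network.substrate_forms)
    for s in network.substrate_forms:
        x[network.species_index[s]] = w
    for e in network.enzymes:
        x[network.species_index[e]] = params.totals.enzyme_totals[e]
    return x


def numeric_breaking_test(
    spec: NetworkSpec,
    params: ParameterSet,
    inv: Involution | None = None,
    a_range: tuple[float, float] | None = None,
    options: ContinuationOptions | None = None,
    case: str = "case1",
) -> BreakingReport:
    """Continue the symmetric branch over ``a_range`` and report whether the
    antisymmetric test function crosses zero (a symmetry-breaking pitchfork).

    Default scan range: A_Total from 1e-2 x to DEFAULT_SCAN_FACTOR x the
    largest enzyme total.  This is the oracle all analytic criteria are
    validated against; a negative answer is conclusive only up to the cap.
    """
    if inv is None:
        inv = involution_for(spec, case)
    network = inv.network
    r = symmetry_residual(params, inv)
    if r > _SYM_CONTRACT:
        raise ValueError(f"numeric_breaking_test requires symmetric parameters (residual {r:.3g})")
    if a_range is None:
        emax = max(params.totals.enzyme_totals.values())
        a_range = (1e-2 * emax, DEFAULT_SCAN_FACTOR * emax)
    p0 = params.replace_totals(params.totals.with_substrate(a_range[0]))
    start = solve_steady(network, p0, _symmetric_start(network, p0))
    if not start.converged:
        return BreakingReport(False, None, Branch(network, p0, []), True,
                              f"no symmetric steady state at range start: {start.message}")
    branch = continue_branch(
        network, p0, a_range, start.x, options=options, involution=inv,
        enforce_symmetry=True,
    )
    pfs = [b for b in branch.bifurcations if b.kind == "pitchfork"]
    return BreakingReport(
        bool(pfs), pfs[0].a_total if pfs else None, branch, branch.truncated,
        branch.message,
    )
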