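"""Steady-state solving and the multistart sweep used as numerical oracle.

``solve_steady`` is a damped Newton iteration on the reduced system (one
equation per conservation law is absorbed by the reduction, which is
equivalent to replacing it with the conservation constraint).
``sweep_steady_states`` seeds Newton from random admissible partitions of the
totals and deduplicates the converged solutions; it serves as the brute-force
cross-check for the continuation module and for the analytic breaking criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ReducedSystem
from .networks import ParameterSet, ReactionNetwork

__all__ = [
    "SteadyResult",
    "solve_steady",
    "newton_reduced",
    "classify_stability",
    "sweep_steady_states",
    "SweepSolution",
]

DEDUP_RTOL = 1e-6  # relative L-inf threshold for treating two states as equal


@dataclass
class SteadyResult:
    converged: bool
    x: np.ndarray | None  # full state, clipped to nonnegative
    y: np.ndarray | None  # reduced coordinates (unclipped)
    residual: float
    iterations: int
    message: str = ""


def newton_reduced(
    sys: ReducedSystem,
    y0: np.ndarray,
    tol_factor: float = 1e-10,
    max_iter: int = 60,
) -> SteadyResult:
    """Damped Newton on the reduced steady-state system from reduced guess y0."""
    scale = sys.rate_scale()
    tol = tol_factor * scale
    y = np.asarray(y0, dtype=float).copy()
    f = sys.f(y)
    nf = float(np.max(np.abs(f)))
    for it in range(1, max_iter + 1):
        if nf <= tol:
            y, nf = _polish(sys, y, f, nf)
            return _finish(sys, y, nf, it - 1)
        J = sys.jac(y)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            return SteadyResult(False, None, None, nf, it, "non-finite Newton step")
        lam = 1.0
        while lam >= 1.0 / 1024.0:
            y_new = y + lam * step
            f_new = sys.f(y_new)
            nf_new = float(np.max(np.abs(f_new)))
            if np.isfinite(nf_new) and nf_new < nf * (1.0 - 0.1 * lam) + tol:
                break
            lam *= 0.5
        else:
            return SteadyResult(False, None, None, nf, it, "line search stalled")
        y, f, nf = y_new, f_new, nf_new
    if nf <= tol:
        return _finish(sys, y, nf, max_iter)
    return SteadyResult(False, None, None, nf, max_iter, "max iterations")


def _polish(sys: ReducedSystem, y: np.ndarray, f: np.ndarray, nf: float):
    """Extra full Newton steps down to the machine floor, so that states in
    stiff regimes are sharp enough for the sweep's deduplication."""
    for _ in range(4):
        try:
            step = np.linalg.solve(sys.jac(y), -f)
        except np.linalg.LinAlgError:
            break
        y_new = y + step
        f_new = sys.f(y_new)
        nf_new = float(np.max(np.abs(f_new)))
        if not np.isfinite(nf_new) or nf_new >= 0.5 * nf:
            break
        y, f, nf = y_new, f_new, nf_new
    return y, nf


def _finish(sys: ReducedSystem, y: np.ndarray, nf: float, it: int) -> SteadyResult:
    x = sys.lift(y)
    neg_tol = 1e-8 * sys.model.characteristic_conc()
    if np.min(x) < -neg_tol:
        return SteadyResult(False, None, None, nf, it, "negative concentrations")
    return SteadyResult(True, np.clip(x, 0.0, None), y, nf, it)


def ptc_reduced(
    sys: ReducedSystem,
    y0: np.ndarray,
    max_iter: int = 400,
) -> SteadyResult:
    """Pseudo-transient continuation: implicit-Euler-like damping that follows
    the flow, so from a basin of attraction it converges to the *stable* steady
    state there (plain Newton's basins are fractal and mostly find the
    symmetric state).  Finishes with a Newton polish."""
    scale = sys.rate_scale()
    rate = sys.model.characteristic_rate()
    y = np.asarray(y0, dtype=float).copy()
    f = sys.f(y)
    nf = float(np.max(np.abs(f)))
    dt = 0.1 / rate
    n = len(y)
    eye = np.eye(n)
    for it in range(max_iter):
        if nf <= 1e-6 * scale:
            break
        J = sys.jac(y)
        try:
            step = np.linalg.solve(eye / dt - J, f)
        except np.linalg.LinAlgError:
            dt *= 0.25
            continue
        y_new = y + step
        f_new = sys.f(y_new)
        nf_new = float(np.max(np.abs(f_new)))
        if not np.isfinite(nf_new) or nf_new > 3.0 * nf:
            dt *= 0.25
            if dt < 1e-12 / rate:
                return SteadyResult(False, None, None, nf, it, "PTC stalled")
            continue
        dt = min(dt * (1.6 if nf_new <= nf else 0.7), 1e6 / rate)
        y, f, nf = y_new, f_new, nf_new
    return newton_reduced(sys, y)


def solve_steady(
    network: ReactionNetwork, params: ParameterSet, guess: np.ndarray
) -> SteadyResult:
    """Solve for a steady state from a full-coordinate guess respecting totals."""
    sys = ReducedSystem(network, params)
    y0 = sys.reduction.reduce_state(np.asarray(guess, dtype=float))
    return newton_reduced(sys, y0)


def classify_stability(
    network: ReactionNetwork, params: ParameterSet, x: np.ndarray
) -> str:
    """'stable' | 'unstable' | 'marginal' from reduced-Jacobian eigenvalues."""
    sys = ReducedSystem(network, params)
    y = sys.reduction.reduce_state(np.asarray(x, dtype=float))
    resid = float(np.max(np.abs(sys.f(y))))
    if resid > 1e-6 * sys.rate_scale():
        raise ValueError(f"state is not a steady state (residual {resid:.3g})")
    return stability_from_eigs(np.linalg.eigvals(sys.jac(y)), sys.model.characteristic_rate())


def stability_from_eigs(eigs: np.ndarray, char_rate: float) -> str:
    tau = 1e-8 * char_rate
    re = eigs.real
    if np.all(re < -tau):
        return "stable"
    if np.any(re > tau):
        return "unstable"
    return "marginal"


@dataclass
class SweepSolution:
    x: np.ndarray
    stability: str


def _random_start(sys: ReducedSystem, rng: np.random.Generator) -> np.ndarray:
    """Admissible start: Dirichlet split of the substrate pool over substrate
    forms, all enzymes free, no complexes."""
    net = sys.network
    x = np.zeros(net.n_species)
    w = rng.dirichlet(np.ones(len(net.substrate_forms)))
    for s, wi in zip(net.substrate_forms, w):
        x[net.species_index[s]] = wi * sys.totals.substrate_total
    for e in net.enzymes:
        x[net.species_index[e]] = sys.totals.enzyme_totals[e]
    return x


def sweep_steady_states(
    network: ReactionNetwork,
    params: ParameterSet,
    n_starts: int = 64,
    seed: int = 0,
    classify: bool = True,
) -> list[SweepSolution]:
    """Multistart Newton sweep; deduplicated, canonically sorted solutions."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sys = ReducedSystem(network, params)
    rng = np.random.default_rng(seed)
    conc = sys.model.characteristic_conc()
    char_rate = sys.model.characteristic_rate()
    found: list[np.ndarray] = []

    def record(res: SteadyResult) -> None:
        if res.converged and not any(
            np.max(np.abs(res.x - g)) <= DEDUP_RTOL * conc for g in found
        ):
            found.append(res.x)

    for _ in range(n_starts):
        y0 = sys.reduction.reduce_state(_random_start(sys, rng))
        # plain Newton reaches unstable states; flow-following PTC reaches the
        # stable attractor of the start's basin
        record(newton_reduced(sys, y0))
        record(ptc_reduced(sys, y0))
    found.sort(key=lambda x: tuple(np.round(x, 12)))
    out = []
    for x in found:
        if classify:
            y = sys.reduction.reduce_state(x)
            stab = stability_from_eigs(np.linalg.eigvals(sys.jac(y)), char_rate)
        else:
            stab = "unknown"
        out.append(SweepSolution(x, stab))
    return out
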