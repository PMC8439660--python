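"""Mass-action dynamics: right-hand side, analytic Jacobian, reduction, integration.

The ODE system is pure mass action over the elementary reactions of a
:class:`~symphos.networks.ReactionNetwork`.  Linear conservation laws (one per
substrate pool, one per enzyme) are removed by eliminating the unmodified
substrate and each free enzyme, leaving the modified forms — which carry the
concentration-robustness invariants of interest — as explicit coordinates.
Time integration is performed on the reduced system, so conserved totals are
preserved exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .networks import ParameterSet, ReactionNetwork, Totals

__all__ = [
    "CompiledModel",
    "Reduction",
    "ReducedSystem",
    "rhs",
    "jacobian",
    "reduce",
    "Trajectory",
    "simulate",
    "detect_oscillations",
    "OscillationReport",
]


class CompiledModel:
    """A network with bound rate constants, in array form for fast evaluation."""

    def __init__(self, network: ReactionNetwork, params: ParameterSet):
        self.network = network
        self.params = params
        self.k = network.rate_constants(params).astype(float)
        n_r = network.n_reactions
        idx = network.species_index
        r1 = np.empty(n_r, dtype=np.intp)
        r2 = np.full(n_r, -1, dtype=np.intp)
        for j, r in enumerate(network.reactions):
            r1[j] = idx[r.reactants[0]]
            if len(r.reactants) == 2:
                r2[j] = idx[r.reactants[1]]
        self.r1, self.r2 = r1, r2
        self.bimol = r2 >= 0
        self.S = network.stoich_matrix.astype(float)

    def rates(self, x: np.ndarray) -> np.ndarray:
        v = self.k * x[self.r1]
        v[self.bimol] *= x[self.r2[self.bimol]]
        return v

    def rhs_full(self, x: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(x)

    def jac_full(self, x: np.ndarray) -> np.ndarray:
        n_r, n_s = len(self.k), self.S.shape[0]
        dR = np.zeros((n_r, n_s))
        g1 = self.k.copy()
        g1[self.bimol] *= x[self.r2[self.bimol]]
        np.add.at(dR, (np.arange(n_r), self.r1), g1)
        bi = np.flatnonzero(self.bimol)
        np.add.at(dR, (bi, self.r2[bi]), self.k[bi] * x[self.r1[bi]])
        return self.S @ dR

    def characteristic_rate(self) -> float:
        """Scale for eigenvalue/residual thresholds: the largest first-order
        rate (unbinding/catalysis, and binding scaled by the largest total)."""
        cap = self.characteristic_conc()
        k = self.k.copy()
        k[self.bimol] *= cap
        return float(np.max(k))

    def characteristic_conc(self) -> float:
        t = self.params.totals
        return float(max(t.substrate_total, max(t.enzyme_totals.values())))


def rhs(network: ReactionNetwork, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """Per-species time derivative at state ``x`` (full coordinates)."""
    return CompiledModel(network, params).rhs_full(np.asarray(x, dtype=float))


def jacobian(network: ReactionNetwork, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at ``x``."""
    return CompiledModel(network, params).jac_full(np.asarray(x, dtype=float))


class Reduction:
    """Elimination of one species per conservation law.

    Eliminated: the unmodified substrate form and every free enzyme.  ``lift``
    reconstructs a full state from reduced coordinates and totals;
    ``reduce_state`` is its left inverse on admissible states.
    """

    def __init__(self, network: ReactionNetwork):
        self.network = network
        elim = [network.substrate_forms[0]] + list(network.enzymes)
        self.eliminated = elim
        self.retained = [s for s in network.species if s not in elim]
        idx = network.species_index
        self.retained_idx = np.array([idx[s] for s in self.retained], dtype=np.intp)
        self.elim_idx = np.array([idx[s] for s in elim], dtype=np.intp)
        self.n_reduced = len(self.retained)
        n = network.n_species
        # lift(y) = L y + c,  c = T @ totals_vector (identity placement)
        L = np.zeros((n, self.n_reduced))
        L[self.retained_idx, np.arange(self.n_reduced)] = 1.0
        cons = network.conservation_basis
        sub0 = elim[0]
        v = cons["substrate"].astype(float)
        L[idx[sub0], :] = -v[self.retained_idx]
        for e in network.enzymes:
            w = cons[e].astype(float)
            L[idx[e], :] = -w[self.retained_idx]
        self.L = L
        self._pool_names = ["substrate"] + list(network.enzymes)

    def _offset(self, totals: Totals) -> np.ndarray:
        c = np.zeros(self.network.n_species)
        c[self.elim_idx[0]] = totals.substrate_total
        for i, e in enumerate(self.network.enzymes, start=1):
            c[self.elim_idx[i]] = totals.enzyme_totals[e]
        return c

    def lift(self, y: np.ndarray, totals: Totals) -> np.ndarray:
        return self.L @ y + self._offset(totals)

    def reduce_state(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)[self.retained_idx]


def reduce(network: ReactionNetwork, totals: Totals | None = None) -> Reduction:
    """Build the conservation-based reduction record for a network."""
    return Reduction(network)


class ReducedSystem:
    """The reduced steady-state/flow map G(y) = rhs(lift(y))[retained]."""

    def __init__(self, network: ReactionNetwork, params: ParameterSet):
        params.validate_for(network)
        self.model = CompiledModel(network, params)
        self.reduction = Reduction(network)
        self.totals = params.totals
        self.network = network
        self.params = params

    def with_substrate(self, a_total: float) -> "ReducedSystem":
        out = ReducedSystem.__new__(ReducedSystem)
        out.model = self.model
        out.reduction = self.reduction
        out.network = self.network
        out.totals = self.totals.with_substrate(a_total)
        out.params = self.params.replace_totals(out.totals)
        return out

    def f(self, y: np.ndarray) -> np.ndarray:
        x = self.reduction.lift(y, self.totals)
        return self.model.rhs_full(x)[self.reduction.retained_idx]

    def jac(self, y: np.ndarray) -> np.ndarray:
        x = self.reduction.lift(y, self.totals)
        J = self.model.jac_full(x)
        return J[self.reduction.retained_idx] @ self.reduction.L

    def df_dA(self, y: np.ndarray) -> np.ndarray:
        """Derivative of G w.r.t. the total substrate concentration."""
        x = self.reduction.lift(y, self.totals)
        J = self.model.jac_full(x)
        sub0 = self.reduction.elim_idx[0]
        return J[self.reduction.retained_idx, sub0]

    def lift(self, y: np.ndarray) -> np.ndarray:
        return self.reduction.lift(y, self.totals)

    def rate_scale(self) -> float:
        return self.model.characteristic_rate() * self.model.characteristic_conc()


# ---------------------------------------------------------------------------
# time integration


@dataclass
class Trajectory:
    """Integrated trajectory in full species coordinates."""

    network: ReactionNetwork
    times: np.ndarray  # (n_t,)
    states: np.ndarray  # (n_t, n_species)
    success: bool
    message: str = ""

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.network.species_index[name]]


class IntegrationError(RuntimeError):
    pass


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    init: np.ndarray,
    t_end: float,
    rtol: float = 1e-8,
    atol: float | None = None,
    n_eval: int = 2000,
    method: str = "LSODA",
) -> Trajectory:
    """Stiff-capable integration from a full-coordinate initial state.

    Integration happens in reduced coordinates, so all conserved totals are
    held exactly; the returned trajectory is lifted back to full coordinates.
    """
    sys = ReducedSystem(network, params)
    if atol is None:
        atol = 1e-12 * sys.model.characteristic_conc()
    y0 = sys.reduction.reduce_state(np.asarray(init, dtype=float))
    sol = solve_ivp(
        lambda t, y: sys.f(y),
        (0.0, t_end),
        y0,
        method=method,
        jac=lambda t, y: sys.jac(y),
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_end, n_eval),
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}"
        )
    states = np.stack([sys.lift(y) for y in sol.y.T])
    return Trajectory(network, sol.t, states, True, sol.message)


@dataclass
class OscillationReport:
    sustained: bool
    conclusive: bool
    period: float | None
    amplitude: dict  # species -> peak-to-trough amplitude on the tail
    message: str = ""


def detect_oscillations(
    traj: Trajectory, settle_fraction: float = 0.5, min_periods: int = 5
) -> OscillationReport:
    """Classify the tail of a trajectory as sustained oscillation or not.

    Peaks are detected on the post-settle tail of the species with the largest
    residual variation.  The oscillation is *sustained* when the relative
    peak-height variation is below 5% and at least four inter-peak intervals
    agree to within 5%; the period is the mean inter-peak interval.  A tail too
    short to contain ``min_periods`` putative periods yields an inconclusive
    report (distinct from "not sustained").
    """
    n0 = int(len(traj.times) * settle_fraction)
    t, X = traj.times[n0:], traj.states[n0:]
    spans = X.max(axis=0) - X.min(axis=0)
    scale = max(float(np.max(X)), 1e-300)
    i_best = int(np.argmax(spans))
    x = X[:, i_best]
    amplitude = {s: float(spans[j]) for j, s in enumerate(traj.network.species)}
    if spans[i_best] < 1e-6 * scale:
        return OscillationReport(False, True, None, amplitude, "converged (flat tail)")
    peaks, _ = find_peaks(x, prominence=0.1 * spans[i_best])
    if len(peaks) < min_periods:
        return OscillationReport(
            False, False, None, amplitude, f"only {len(peaks)} peaks in tail; inconclusive"
        )
    tp = t[peaks]
    heights = x[peaks]
    intervals = np.diff(tp)
    height_var = float(np.ptp(heights) / max(np.mean(heights), 1e-300))
    rel_dev = np.abs(intervals - np.mean(intervals)) / np.mean(intervals)
    n_equal = int(np.sum(rel_dev < 0.05))
    sustained = height_var < 0.05 and n_equal >= 4
    period = float(np.mean(intervals)) if sustained else None
    return OscillationReport(
        sustained, True, period, amplitude,
        f"{len(peaks)} peaks, height variation {height_var:.3g}",
    )
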