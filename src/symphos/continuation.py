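"""Pseudo-arclength continuation in total substrate and bifurcation detection.

The continuation parameter is the total substrate concentration A_Total, which
enters the reduced system only through the eliminated unmodified-substrate
coordinate.  Branches are traced with a tangent (Keller) predictor and a
bordered Newton corrector, with adaptive step control, so folds are traversed.

Bifurcations are located by sign changes of test functions between accepted
points, refined by bisection:

* **pitchfork** — on a symmetry-invariant branch, the leading real eigenvalue
  of the Jacobian restricted to the antisymmetric subspace of the involution;
* **hopf** — the largest real part over complex-conjugate eigenvalue pairs;
* **fold** — the A_Total component of the branch tangent;
* **transcritical** — a real eigenvalue crossing with no accompanying fold
  (used in the non-symmetric concentration-robustness scan, where two distinct
  branches cross and exchange stability).

Symmetric branches are continued with every Newton iterate projected back
onto the symmetric manifold, so roundoff cannot push the corrector onto an
emanating asymmetric branch and the antisymmetric test function stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import ReducedSystem
from .networks import ParameterSet, ReactionNetwork
from .steady import newton_reduced, stability_from_eigs
from .symmetry import Involution, reduced_involution, state_residual

__all__ = [
    "ContinuationOptions",
    "BranchPoint",
    "BifurcationPoint",
    "Branch",
    "continue_branch",
    "detect_bifurcations",
    "switch_branch",
    "classify_pitchfork",
]

_SYM_TOL = 1e-6  # relative state residual below which a point counts as symmetric


@dataclass
class ContinuationOptions:
    ds0_rel: float = 1e-2  # initial step, relative to the A_Total range
    ds_min_rel: float = 1e-7
    ds_max_rel: float = 5e-2
    max_steps: int = 3000
    tol_factor: float = 1e-10
    bisect_rtol: float = 1e-8  # relative A_Total tolerance of refined events
    corrector_max_iter: int = 12
    compute_eigs: bool = True


@dataclass
class BranchPoint:
    a_total: float
    y: np.ndarray
    x: np.ndarray
    stability: str
    eigs: np.ndarray | None
    tests: dict
    tangent: np.ndarray | None = None  # (n_red + 1,), last entry = dA/ds


@dataclass
class BifurcationPoint:
    kind: str  # "pitchfork" | "hopf" | "fold" | "transcritical"
    a_total: float
    x: np.ndarray
    y: np.ndarray
    classification: str = "n/a"  # "supercritical" | "subcritical" | "n/a"
    eigenvalue: complex = 0.0
    eigenvector: np.ndarray | None = None  # critical direction, reduced coords


@dataclass
class Branch:
    network: ReactionNetwork
    params: ParameterSet  # totals.substrate_total is the range start
    points: list[BranchPoint]
    bifurcations: list[BifurcationPoint] = field(default_factory=list)
    involution: Involution | None = None
    truncated: bool = False
    message: str = ""

    @property
    def a_values(self) -> np.ndarray:
        return np.array([p.a_total for p in self.points])

    @property
    def is_symmetric(self) -> bool:
        if self.involution is None:
            return False
        return all(
            state_residual(p.x, self.involution) <= _SYM_TOL for p in self.points
        )

    def species_values(self, name: str) -> np.ndarray:
        i = self.network.species_index[name]
        return np.array([p.x[i] for p in self.points])

    def max_state_residual(self) -> float:
        if self.involution is None:
            return float("nan")
        return max(state_residual(p.x, self.involution) for p in self.points)


class _SymmetricChart:
    """Projection onto (and tests against) the symmetric manifold, per A_Total."""

    def __init__(self, sys: ReducedSystem, inv: Involution):
        self.inv = inv
        self.red = sys.reduction
        self.M, _ = reduced_involution(inv, sys.reduction, sys.totals)
        from scipy.linalg import null_space

        self.Va = null_space(self.M + np.eye(self.M.shape[0]))  # antisymmetric
        self.Va_pinv = np.linalg.pinv(self.Va)

    def offset(self, sys: ReducedSystem) -> np.ndarray:
        n = self.red.n_reduced
        return self.red.reduce_state(
            self.inv.apply(self.red.lift(np.zeros(n), sys.totals))
        )

    def project(self, y: np.ndarray, sys: ReducedSystem) -> np.ndarray:
        return 0.5 * (y + self.M @ y + self.offset(sys))

    def antisym_block(self, J: np.ndarray) -> np.ndarray:
        return self.Va_pinv @ J @ self.Va


def _signed_root_det(A: np.ndarray) -> float:
    """sign(det A) * |det A|^(1/n): eigenvalue-scaled, sign-robust test value.

    The determinant flips sign exactly when a *real* eigenvalue crosses zero;
    a complex pair crossing the axis (or turning real away from zero) leaves
    it unchanged, so this cannot produce spurious steady-state bifurcations.
    """
    n = A.shape[0]
    if n == 0:
        return 1.0
    sign, logabs = np.linalg.slogdet(A)
    if sign == 0.0:
        return 0.0
    return float(sign * np.exp(logabs / n))


def _tests(
    sys: ReducedSystem, y: np.ndarray, chart: _SymmetricChart | None
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Eigen-based test functions at a point; returns (tests, eigs, J)."""
    J = sys.jac(y)
    eigs = np.linalg.eigvals(J)
    rate = sys.model.characteristic_rate()
    im_tol = 1e-8 * rate
    complex_mask = np.abs(eigs.imag) > im_tol
    tests: dict = {}
    if np.any(complex_mask):
        tests["hopf"] = float(np.max(eigs.real[complex_mask]))
    else:
        tests["hopf"] = None
    tests["real_det"] = _signed_root_det(J)
    if chart is not None:
        Ja = chart.antisym_block(J)
        tests["pitchfork"] = _signed_root_det(Ja)
        tests["antisym_pos"] = int(np.sum(np.linalg.eigvals(Ja).real > im_tol))
    else:
        tests["pitchfork"] = None
    return tests, eigs, J


def _corrector(
    z_pred: np.ndarray,
    tangent: np.ndarray,
    base_sys: ReducedSystem,
    chart: _SymmetricChart | None,
    tol: float,
    max_iter: int,
):
    """Bordered Newton for [G(y, A) = 0; tangent . (z - z_pred) = 0]."""
    z = z_pred.copy()
    n = len(z) - 1
    for it in range(max_iter):
        sys = base_sys.with_substrate(z[-1])
        y = z[:n]
        if chart is not None:
            y = chart.project(y, sys)
            z = np.append(y, z[-1])
        g = sys.f(y)
        r = np.append(g, tangent @ (z - z_pred))
        if float(np.max(np.abs(g))) <= tol and abs(r[-1]) <= 1e-12 * max(
            1.0, float(np.max(np.abs(z)))
        ):
            # physical branches only: a large predictor step can land the
            # corrector on a spurious negative-concentration solution sheet
            conc = max(abs(z[-1]), sys.model.characteristic_conc())
            if float(np.min(sys.lift(y))) < -1e-6 * conc:
                return z, False
            return z, True
        J = sys.jac(y)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J
        A[:n, n] = sys.df_dA(y)
        A[n, :] = tangent
        try:
            dz = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            dz = np.linalg.lstsq(A, -r, rcond=None)[0]
        if not np.all(np.isfinite(dz)):
            return z, False
        z = z + dz
        if z[-1] <= 0:
            return z, False
    sys = base_sys.with_substrate(z[-1])
    y = chart.project(z[:n], sys) if chart is not None else z[:n]
    ok = float(np.max(np.abs(sys.f(y)))) <= tol
    return np.append(y, z[-1]), ok


def _tangent_at(
    base_sys: ReducedSystem, z: np.ndarray, prev_tangent: np.ndarray
) -> np.ndarray:
    """Null tangent of the bordered Jacobian, oriented along prev_tangent."""
    n = len(z) - 1
    sys = base_sys.with_substrate(z[-1])
    J = sys.jac(z[:n])
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = J
    A[:n, n] = sys.df_dA(z[:n])
    A[n, :] = prev_tangent
    rhs_v = np.zeros(n + 1)
    rhs_v[n] = 1.0
    try:
        t = np.linalg.solve(A, rhs_v)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, rhs_v, rcond=None)[0]
    nt = float(np.linalg.norm(t))
    if nt == 0 or not np.isfinite(nt):
        return prev_tangent
    t = t / nt
    if t @ prev_tangent < 0:
        t = -t
    return t


def _solve_at_A(
    base_sys: ReducedSystem,
    a_total: float,
    y_guess: np.ndarray,
    chart: _SymmetricChart | None,
):
    sys = base_sys.with_substrate(a_total)
    y = y_guess.copy()
    scale = sys.rate_scale()
    tol = 1e-10 * scale
    for _ in range(60):
        if chart is not None:
            y = chart.project(y, sys)
        f = sys.f(y)
        if float(np.max(np.abs(f))) <= tol:
            return sys, y, True
        J = sys.jac(y)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            return sys, y, False
        y = y + step
    return sys, y, float(np.max(np.abs(sys.f(y)))) <= tol


def continue_branch(
    network: ReactionNetwork,
    params: ParameterSet,
    a_range: tuple[float, float],
    start: np.ndarray,
    options: ContinuationOptions | None = None,
    involution: Involution | None = None,
    enforce_symmetry: bool | None = None,
    initial_direction: np.ndarray | None = None,
    start_a: float | None = None,
) -> Branch:
    """Trace a steady-state branch over ``a_range`` from a starting state.

    ``start`` is a full-coordinate steady state at ``start_a`` (by default
    ``a_range[0]``; it may lie anywhere inside the range, e.g. when following
    a branch emanating from an interior bifurcation).  It is re-polished by
    Newton first.  If an involution is given and the start lies
    on its symmetric manifold, the branch is continued inside that manifold
    and the antisymmetric pitchfork test is monitored.
    """
    opts = options or ContinuationOptions()
    a_lo, a_hi = float(min(a_range)), float(max(a_range))
    span = a_hi - a_lo
    if start_a is None:
        start_a = float(a_range[0])
    base = ReducedSystem(network, params).with_substrate(start_a)
    red = base.reduction

    chart = None
    if involution is not None:
        if enforce_symmetry is None:
            enforce_symmetry = state_residual(np.asarray(start, float), involution) <= _SYM_TOL
        if enforce_symmetry:
            chart = _SymmetricChart(base, involution)

    res = newton_reduced(base, red.reduce_state(np.asarray(start, dtype=float)))
    if not res.converged:
        return Branch(network, params, [], involution=involution, truncated=True,
                      message=f"start is not a steady state: {res.message}")
    y = chart.project(res.y, base) if chart is not None else res.y
    z = np.append(y, start_a)

    n = red.n_reduced
    t0 = np.zeros(n + 1)
    t0[-1] = 1.0 if a_range[1] >= a_range[0] else -1.0
    if initial_direction is not None:
        t0 = initial_direction / np.linalg.norm(initial_direction)
    tangent = _tangent_at(base, z, t0)

    rate = base.model.characteristic_rate()
    tol = opts.tol_factor * base.rate_scale()
    conc0 = base.model.characteristic_conc()
    # local cap: never step further than a fraction of the current scale, so
    # wide scan ranges are traversed geometrically rather than skipped over
    step_cap = lambda lam: 0.25 * max(abs(lam), conc0)
    ds = min(opts.ds0_rel * span, step_cap(start_a))
    ds_min, ds_max = opts.ds_min_rel * span, opts.ds_max_rel * span

    points: list[BranchPoint] = []

    def accept(zp: np.ndarray, tg: np.ndarray | None) -> None:
        sys = base.with_substrate(zp[-1])
        tests, eigs, _ = _tests(sys, zp[:n], chart)
        stab = stability_from_eigs(eigs, rate)
        points.append(
            BranchPoint(float(zp[-1]), zp[:n].copy(), sys.lift(zp[:n]), stab, eigs, tests, tg)
        )

    accept(z, tangent)
    truncated, message = False, ""
    for _ in range(opts.max_steps):
        ds_eff = min(ds, step_cap(z[-1]))
        z_pred = z + ds_eff * tangent
        z_new, ok = _corrector(z_pred, tangent, base, chart, tol,
                               opts.corrector_max_iter)
        if not ok:
            ds *= 0.5
            if ds < ds_min:
                truncated, message = True, "corrector failed at minimum step"
                break
            continue
        step_vec = z_new - z
        norm_step = float(np.linalg.norm(step_vec))
        if norm_step == 0.0:
            ds = min(ds * 2.0, ds_max)
            continue
        new_tangent = _tangent_at(base, z_new, step_vec / norm_step)
        # clamp to the requested range: land exactly on the boundary
        if z_new[-1] > a_hi + 1e-12 * span or z_new[-1] < a_lo - 1e-12 * span:
            bound = a_hi if z_new[-1] > a_hi else a_lo
            sys_b, y_b, okb = _solve_at_A(base, bound, z[:n], chart)
            if okb:
                accept(np.append(y_b, bound), None)
            break
        z, tangent = z_new, new_tangent
        accept(z, tangent)
        ds = min(ds * 1.3, ds_max)
    else:
        truncated, message = True, "max continuation steps reached"

    branch = Branch(network, params, points, involution=involution,
                    truncated=truncated, message=message)
    branch.bifurcations = detect_bifurcations(
        branch, involution if chart is not None else None, opts
    )
    return branch


# ---------------------------------------------------------------------------
# bifurcation detection


def _bisect_event(
    base: ReducedSystem,
    chart: _SymmetricChart | None,
    p0: BranchPoint,
    p1: BranchPoint,
    key: str,
    rtol: float,
):
    """Bisection in A_Total between two accepted points bracketing a sign
    change of test function ``key``; assumes A_Total is monotone in between."""
    a0, a1 = p0.a_total, p1.a_total
    y0, y1 = p0.y, p1.y
    f0 = p0.tests[key]
    for _ in range(80):
        if abs(a1 - a0) <= rtol * max(abs(a0), abs(a1), 1e-300):
            break
        am = 0.5 * (a0 + a1)
        w = (am - p0.a_total) / (p1.a_total - p0.a_total)
        sys, ym, ok = _solve_at_A(base, am, (1 - w) * p0.y + w * p1.y, chart)
        if not ok:
            sys, ym, ok = _solve_at_A(base, am, y0, chart)
            if not ok:
                break
        tm, _, _ = _tests(sys, ym, chart)
        fm = tm[key]
        if fm is None:
            break
        if (fm > 0) == (f0 > 0):
            a0, y0, f0 = am, ym, fm
        else:
            a1, y1 = am, ym
    am = 0.5 * (a0 + a1)
    sys, ym, ok = _solve_at_A(base, am, y0, chart)
    return sys, ym, am


def _refine_fold(base, chart, p0: BranchPoint, p1: BranchPoint, rtol: float):
    """Localize a fold by arclength bisection on the tangent's dA/ds sign."""
    z0 = np.append(p0.y, p0.a_total)
    z1 = np.append(p1.y, p1.a_total)
    t0, t1 = p0.tangent, p1.tangent
    s0 = t0[-1]
    for _ in range(60):
        if abs(z1[-1] - z0[-1]) <= rtol * max(abs(z0[-1]), 1e-300) and (
            np.linalg.norm(z1 - z0) <= 1e-6 * max(np.linalg.norm(z0), 1e-300)
        ):
            break
        sec = z1 - z0
        nsec = float(np.linalg.norm(sec))
        if nsec == 0:
            break
        sec = sec / nsec
        z_pred = 0.5 * (z0 + z1)
        zm, ok = _corrector(z_pred, sec, base, chart, 1e-10 * base.rate_scale(), 15)
        if not ok:
            break
        tm = _tangent_at(base, zm, sec)
        if (tm[-1] > 0) == (s0 > 0):
            z0, t0 = zm, tm
        else:
            z1, t1 = zm, tm
    zm = 0.5 * (z0 + z1)
    sys = base.with_substrate(zm[-1])
    return sys, zm[: len(zm) - 1], float(zm[-1])


def detect_bifurcations(
    branch: Branch,
    involution: Involution | None = None,
    options: ContinuationOptions | None = None,
) -> list[BifurcationPoint]:
    """Scan a branch for test-function sign changes and refine each event."""
    if len(branch.points) < 3:
        return []
    opts = options or ContinuationOptions()
    base = ReducedSystem(branch.network, branch.params)
    chart = None
    if involution is not None:
        if not branch.is_symmetric:
            raise ValueError(
                "a symmetric-branch pitchfork test was requested on a branch "
                "that leaves the symmetric manifold"
            )
        chart = _SymmetricChart(base, involution)
    rate = base.model.characteristic_rate()
    im_tol = 1e-8 * rate
    events: list[BifurcationPoint] = []
    pts = branch.points
    for p0, p1 in zip(pts[:-1], pts[1:]):
        fold_here = (
            p0.tangent is not None
            and p1.tangent is not None
            and p0.tangent[-1] * p1.tangent[-1] < 0
        )
        if chart is not None:
            f0, f1 = p0.tests.get("pitchfork"), p1.tests.get("pitchfork")
            if f0 is not None and f1 is not None and f0 * f1 < 0:
                sys, ym, am = _bisect_event(base, chart, p0, p1, "pitchfork", opts.bisect_rtol)
                J = sys.jac(ym)
                Ja = chart.antisym_block(J)
                ew, ev = np.linalg.eig(Ja)
                i = int(np.argmin(np.abs(ew)))  # the eigenvalue crossing zero
                vec = chart.Va @ ev[:, i].real
                vec /= np.linalg.norm(vec)
                events.append(
                    BifurcationPoint("pitchfork", am, sys.lift(ym), ym,
                                     eigenvalue=complex(ew[i]), eigenvector=vec)
                )
                continue
        f0, f1 = p0.tests.get("hopf"), p1.tests.get("hopf")
        if f0 is not None and f1 is not None and f0 * f1 < 0:
            sys, ym, am = _bisect_event(base, chart, p0, p1, "hopf", opts.bisect_rtol)
            eigs = np.linalg.eigvals(sys.jac(ym))
            cm = np.abs(eigs.imag) > im_tol
            if np.any(cm):
                ev = eigs[cm][np.argmax(eigs.real[cm])]
                # validate: a genuine Hopf has the pair *on* the axis at the
                # refined point (the test value can also jump when a real
                # eigenvalue pair merges into a complex pair off the axis)
                if abs(ev.real) <= 1e-3 * rate and abs(ev.imag) > im_tol:
                    events.append(
                        BifurcationPoint("hopf", am, sys.lift(ym), ym,
                                         eigenvalue=complex(ev))
                    )
                    continue
        if fold_here:
            sys, ym, am = _refine_fold(base, chart, p0, p1, opts.bisect_rtol)
            events.append(BifurcationPoint("fold", am, sys.lift(ym), ym))
            continue
        if chart is None:
            f0, f1 = p0.tests.get("real_det"), p1.tests.get("real_det")
            if f0 is not None and f1 is not None and f0 * f1 < 0:
                sys, ym, am = _bisect_event(base, chart, p0, p1, "real_det", opts.bisect_rtol)
                events.append(
                    BifurcationPoint("transcritical", am, sys.lift(ym), ym)
                )
    events.sort(key=lambda e: e.a_total)
    return events


# ---------------------------------------------------------------------------
# branch switching and pitchfork classification


class BranchSwitchError(RuntimeError):
    pass


def switch_branch(
    network: ReactionNetwork,
    params: ParameterSet,
    pf: BifurcationPoint,
    direction: int,
    a_range: tuple[float, float],
    involution: Involution,
    options: ContinuationOptions | None = None,
) -> Branch:
    """Follow an asymmetric branch emanating from a pitchfork.

    The corrector is seeded with ``pf.state + eps * direction * v`` where ``v``
    is the antisymmetric critical eigenvector; ``eps`` is auto-scaled.  The two
    values of ``direction`` (+1/-1) give the two sigma-image branches.
    """
    if pf.kind != "pitchfork":
        raise ValueError("switch_branch requires a pitchfork bifurcation point")
    if pf.eigenvector is None:
        raise ValueError("pitchfork point carries no critical eigenvector")
    opts = options or ContinuationOptions()
    base = ReducedSystem(network, params)
    conc = max(base.model.characteristic_conc(), pf.a_total)
    v = pf.eigenvector * direction
    z_pf = np.append(pf.y, pf.a_total)
    tol = opts.tol_factor * base.with_substrate(pf.a_total).rate_scale()
    seed = None
    # bordered corrector with the antisymmetric amplitude prescribed and
    # A_Total free: the symmetric branch is excluded by construction.  The
    # amplitude of z = (y, A) is its distance from the A-dependent symmetric
    # manifold along the critical eigenvector:
    #   alpha(y, A) = v . (y - M y - b0 - A b1) / 2,
    # a *linear* functional of z (the manifold is affine and drifts with A, so
    # a plain v-inner product would be satisfiable by sliding along the
    # symmetric branch).
    M, b_at = reduced_involution(involution, base.reduction,
                                 base.totals.with_substrate(pf.a_total))
    _, b_at2 = reduced_involution(involution, base.reduction,
                                  base.totals.with_substrate(pf.a_total * 1.5))
    b1_vec = (b_at2 - b_at) / (0.5 * pf.a_total)
    u = 0.5 * (v - M.T @ v)
    t_row = np.append(u, -0.5 * v @ b1_vec)
    t_row = t_row / (u @ v)
    v_row = np.append(v, 0.0)
    for eps in (1e-3, 3e-3, 1e-2, 3e-2, 0.1):
        z_pred = z_pf + eps * conc * v_row
        z_new, ok = _corrector(z_pred, t_row, base, None, tol, 20)
        if not ok or z_new[-1] <= 0:
            continue
        x = base.with_substrate(z_new[-1]).lift(z_new[:-1])
        if np.min(x) < -1e-8 * conc:
            continue
        # accept only a *local* asymmetric solution: remote branches are not
        # the one emanating from this pitchfork
        if state_residual(x, involution) > 10 * _SYM_TOL and abs(
            z_new[-1] - pf.a_total
        ) <= 0.3 * conc:
            seed = (float(z_new[-1]), z_new[:-1])
            break
    if seed is None:
        raise BranchSwitchError("corrector could not leave the symmetric manifold")
    a_seed, y_seed = seed
    init_dir = np.append(y_seed - pf.y, a_seed - pf.a_total)
    if np.linalg.norm(init_dir) == 0.0:
        init_dir = np.append(v, 0.0)
    x_seed = base.with_substrate(a_seed).lift(y_seed)
    # continue both ways from the seed (the branch may emanate backwards
    # through a fold, as it does for a subcritical pitchfork) and merge
    # a single pseudo-arclength run: it follows the emanating branch wherever
    # it leads (for a subcritical pitchfork, backwards through the stabilizing
    # fold and on to large totals)
    branch = continue_branch(
        network, params, (min(a_range), max(a_range)), x_seed,
        options=opts, involution=involution, enforce_symmetry=False,
        initial_direction=init_dir, start_a=a_seed,
    )
    return branch


def classify_pitchfork(
    pf: BifurcationPoint, branches: tuple[Branch, Branch], sym_branch: Branch
) -> str:
    """Supercritical if the asymmetric branches emanate into the side where the
    symmetric state is unstable and are stable at inception; subcritical if
    they emanate toward the stable-symmetric side and start unstable."""
    votes = []
    for br in branches:
        near = sorted(br.points, key=lambda p: abs(p.a_total - pf.a_total))[:6]
        if not near:
            return "inconclusive"
        sides = [np.sign(p.a_total - pf.a_total) for p in near if p.a_total != pf.a_total]
        if not sides:
            return "inconclusive"
        side = np.sign(np.mean(sides))
        stable_frac = np.mean([p.stability == "stable" for p in near])
        votes.append((side, stable_frac))
    # which side of the pitchfork is the symmetric branch unstable on?
    after = [p for p in sym_branch.points if p.a_total > pf.a_total]
    before = [p for p in sym_branch.points if p.a_total < pf.a_total]
    if not after or not before:
        return "inconclusive"
    n_pos = lambda pts: np.mean([
        p.tests.get("antisym_pos", 0) for p in
        sorted(pts, key=lambda q: abs(q.a_total - pf.a_total))[:4]
    ])
    unstable_side = 1.0 if n_pos(after) > n_pos(before) else -1.0
    super_votes = sum(
        1 for side, st in votes if side == unstable_side and st > 0.5
    )
    sub_votes = sum(
        1 for side, st in votes if side == -unstable_side and st < 0.5
    )
    if super_votes == len(votes):
        return "supercritical"
    if sub_votes == len(votes):
        return "subcritical"
    # mixed evidence: fall back on stability at inception
    mean_st = np.mean([st for _, st in votes])
    return "supercritical" if mean_st > 0.5 else "subcritical"
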