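"""Network symmetries as involutions on species, enzymes and arrows.

Three symmetry classes of the double-site networks are represented:

* **Case 1** (``[A00] = [A11]``): the two halves of the modification direction
  mirror each other; kinase arrows pair with phosphatase arrows and each
  kinase pairs with a phosphatase.
* **Case 2** (``[A01] = [A10]``): the two modification legs mirror each other;
  arrows pair within the same enzyme type (kinase with kinase, phosphatase
  with phosphatase).
* **Case 3**: the composition of the two, pairing arrows diagonally
  (e.g. phosphorylation of A00 with dephosphorylation of A11 on the opposite
  leg).

An involution is *derived*, not hard-coded: given the substrate permutation of
the case, each arrow's image is computed and matched against the arrow set,
and the induced enzyme pairing must itself be a bijective involution.  This
is exactly what fails for Case 1/3 in the separate-kinase common-phosphatase
network (two kinases would have to pair with the single phosphatase), which
reproduces the structural impossibility of those symmetries there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .networks import (
    ConfigurationError,
    Dephosphorylation,
    NetworkSpec,
    ParameterSet,
    RateTriplet,
    ReactionNetwork,
    Topology,
    Totals,
    build_network,
)

__all__ = [
    "SymmetryCase",
    "IncompatibilityError",
    "Involution",
    "involution_for",
    "symmetrize",
    "symmetry_residual",
    "state_residual",
    "reduced_involution",
    "antisymmetric_basis",
]

SymmetryCase = str  # "case1" | "case2" | "case3"
_CASES = ("case1", "case2", "case3")


class IncompatibilityError(ConfigurationError):
    """The requested symmetry cannot be accommodated by the network."""


@dataclass(frozen=True)
class Involution:
    """A self-inverse symmetry map of a reaction network."""

    case: str
    network: ReactionNetwork
    species_map: dict  # species id -> species id, over all species
    enzyme_pairs: tuple  # ((e, e'), ...) with e <= e', incl. fixed (e, e)
    arrow_pairs: tuple  # ((a, a'), ...) with a <= a'

    def permutation_matrix(self) -> np.ndarray:
        n = self.network.n_species
        P = np.zeros((n, n))
        idx = self.network.species_index
        for s, t in self.species_map.items():
            P[idx[t], idx[s]] = 1.0
        return P

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Image of a full state vector under the species permutation."""
        idx = self.network.species_index
        out = np.empty_like(x)
        for s, t in self.species_map.items():
            out[idx[t]] = x[idx[s]]
        return out

    def arrow_partner(self, arrow: str) -> str:
        for a, b in self.arrow_pairs:
            if a == arrow:
                return b
            if b == arrow:
                return a
        raise KeyError(arrow)


def _substrate_map(spec: NetworkSpec, case: str) -> dict[str, str]:
    t = spec.topology
    if case not in _CASES:
        raise ConfigurationError(f"unknown symmetry case {case!r}")
    if t in (Topology.random_dsp, Topology.square):
        maps = {
            "case1": {"A00": "A11", "A11": "A00", "A01": "A01", "A10": "A10"},
            "case2": {"A00": "A00", "A11": "A11", "A01": "A10", "A10": "A01"},
            "case3": {"A00": "A11", "A11": "A00", "A01": "A10", "A10": "A01"},
        }
        return maps[case]
    if case != "case1":
        raise IncompatibilityError(
            f"{case} symmetry needs two partial phosphoforms; "
            f"{t.value} accommodates only case1"
        )
    if t is Topology.single_site:
        return {"A": "Ap", "Ap": "A"}
    if t is Topology.ordered_dsp:
        return {"A": "App", "App": "A", "Ap": "Ap"}
    return {"A": "Appp", "Appp": "A", "Ap": "App", "App": "Ap"}  # ordered_tsp


def _arrow_signature(arrow: str) -> tuple[str, str, str, str]:
    parts = arrow.split(":")
    kind = parts[0]
    a, b = parts[1].split(">")
    via = parts[2] if len(parts) > 2 else ""
    return kind, a, b, via


def involution_for(spec: NetworkSpec, case: str) -> Involution:
    """Construct the involution of a symmetry case on a network.

    Raises :class:`IncompatibilityError` when the network cannot carry the
    symmetry (wrong topology, or no consistent enzyme pairing exists).
    """
    network = build_network(spec)
    smap = _substrate_map(spec, case)
    # case1/case3 exchange modification direction (kinase <-> phosphatase
    # arrows); case2 preserves it.
    flips_direction = case in ("case1", "case3")
    kind_image = (
        {"p": "d", "d": "p", "proc": "?"} if flips_direction else {"p": "p", "d": "d", "proc": "proc"}
    )

    by_sig = {}
    for arrow in network.arrows:
        kind, a, b, via = _arrow_signature(arrow)
        by_sig[(kind, a, b, via)] = arrow

    arrow_map: dict[str, str] = {}
    for arrow in network.arrows:
        kind, a, b, via = _arrow_signature(arrow)
        image_sig = (
            kind_image[kind],
            smap[a],
            smap[b],
            "via" + smap["A" + via[3:]][1:] if via else "",
        )
        partner = by_sig.get(image_sig)
        if partner is None:
            raise IncompatibilityError(
                f"{case} maps arrow {arrow!r} onto {image_sig} which is not a "
                f"reaction of {spec.label()}"
            )
        arrow_map[arrow] = partner
    for a, b in arrow_map.items():
        if arrow_map[b] != a:
            raise IncompatibilityError(f"arrow pairing for {case} is not an involution")

    # induced enzyme pairing must be a bijective involution
    emap: dict[str, str] = {}
    for a, b in arrow_map.items():
        ea, eb = network.arrow_enzyme[a], network.arrow_enzyme[b]
        if emap.setdefault(ea, eb) != eb:
            raise IncompatibilityError(
                f"{case} symmetry is not accommodated by {spec.label()}: enzyme "
                f"{ea!r} would have to pair with both {emap[ea]!r} and {eb!r}"
            )
    for e, f in emap.items():
        if emap.get(f) != e:
            raise IncompatibilityError(
                f"{case} enzyme pairing is not an involution on {spec.label()}"
            )

    # full species map: substrates + enzymes + complexes (complex of an arrow
    # maps to the complex of the paired arrow carrying the image substrate)
    species_map = dict(smap)
    species_map.update(emap)
    for c in network.complexes:
        e = network.complex_enzyme[c]
        sub = network.complex_substrate[c]
        a = _complex_arrow(network, c)
        a2 = arrow_map[a]
        e2, sub2 = emap[e], smap[sub]
        target = [
            c2
            for c2 in network.complexes
            if _complex_arrow(network, c2) == a2
            and network.complex_enzyme[c2] == e2
            and network.complex_substrate[c2] == sub2
        ]
        if len(target) != 1:
            raise IncompatibilityError(f"no unique image complex for {c!r} under {case}")
        species_map[c] = target[0]

    enzyme_pairs = tuple(sorted({tuple(sorted((e, f))) for e, f in emap.items()}))
    arrow_pairs = tuple(sorted({tuple(sorted((a, b))) for a, b in arrow_map.items()}))
    return Involution(case, network, species_map, enzyme_pairs, arrow_pairs)


def _complex_arrow(network: ReactionNetwork, c: str) -> str:
    for r in network.reactions:
        if c in r.products and r.role == "bind":
            return r.arrow
        if c in r.reactants and r.role == "cat":
            return r.arrow
    raise KeyError(c)


# ---------------------------------------------------------------------------
# parameter-space projection and residuals


def symmetrize(params: ParameterSet, inv: Involution) -> ParameterSet:
    """Project a parameter set onto the symmetric manifold of ``inv``.

    Paired rate constants and paired enzyme totals are replaced by their
    componentwise geometric means (rate constants live on a log scale, and the
    geometric mean preserves positivity and is idempotent).
    """
    params.validate_for(inv.network)
    triplets = dict(params.triplets)
    for a, b in inv.arrow_pairs:
        if a == b:
            continue
        ta, tb = triplets[a].as_tuple(), triplets[b].as_tuple()
        g = RateTriplet(*(math.sqrt(x * y) for x, y in zip(ta, tb)))
        triplets[a] = triplets[b] = g
    totals = dict(params.totals.enzyme_totals)
    for e, f in inv.enzyme_pairs:
        if e == f:
            continue
        g = math.sqrt(totals[e] * totals[f])
        totals[e] = totals[f] = g
    return ParameterSet(triplets, Totals(params.totals.substrate_total, totals))


def symmetry_residual(params: ParameterSet, inv: Involution) -> float:
    """Max absolute log-ratio over paired constants and paired enzyme totals."""
    params.validate_for(inv.network)
    res = 0.0
    for a, b in inv.arrow_pairs:
        for x, y in zip(params.triplets[a].as_tuple(), params.triplets[b].as_tuple()):
            res = max(res, abs(math.log(x / y)))
    et = params.totals.enzyme_totals
    for e, f in inv.enzyme_pairs:
        res = max(res, abs(math.log(et[e] / et[f])))
    return res


def state_residual(x: np.ndarray, inv: Involution) -> float:
    """Relative asymmetry of a state: max_i |x_i - x_{sigma(i)}| / scale.

    The scale is the substrate pool of the state (sum of substrate forms and
    complexes), the natural concentration scale of the network.
    """
    net = inv.network
    scale = float(net.conservation_basis["substrate"] @ x)
    if scale <= 0:
        scale = max(float(np.max(np.abs(x))), 1e-300)
    return float(np.max(np.abs(x - inv.apply(x))) / scale)


# ---------------------------------------------------------------------------
# reduced-coordinate representation (used by continuation's pitchfork test)


def reduced_involution(inv: Involution, reduction, totals: Totals):
    """Affine representation ``y -> M y + b`` of the involution on reduced
    coordinates.

    Requires symmetric totals (paired enzyme totals equal), otherwise the
    involution does not preserve the admissible affine subspace.
    """
    et = totals.enzyme_totals
    for e, f in inv.enzyme_pairs:
        if abs(math.log(et[e] / et[f])) > 1e-9:
            raise ConfigurationError(
                "reduced involution needs equal totals for paired enzymes "
                f"({e!r}, {f!r})"
            )
    n_red = reduction.n_reduced
    M = np.empty((n_red, n_red))
    b = reduction.reduce_state(inv.apply(reduction.lift(np.zeros(n_red), totals)))
    for j in range(n_red):
        y = np.zeros(n_red)
        y[j] = 1.0
        M[:, j] = reduction.reduce_state(inv.apply(reduction.lift(y, totals))) - b
    return M, b


def antisymmetric_basis(inv: Involution, reduction, totals: Totals) -> np.ndarray:
    """Orthonormal basis (columns) of the -1 eigenspace of the involution on
    reduced coordinates: the directions along which a pitchfork breaks the
    symmetry."""
    M, _ = reduced_involution(inv, reduction, totals)
    return null_space(M + np.eye(M.shape[0]))
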