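"""Reaction networks for multisite phosphorylation.

Builds the family of double/triple-site phosphorylation networks as explicit
mass-action systems: every modification arrow (e.g. ``p:A00>A01``) expands into
elementary binding, unbinding and catalytic reactions of the catalysing enzyme,
so that enzyme sequestration — the sole nonlinearity driving symmetry breaking
in these systems — is represented mechanistically.

Site convention
---------------
Substrate subscripts index sites, leftmost digit first: ``A10`` has site 1
modified, ``A01`` site 2.  In separate-kinase networks kinase ``Ki``
phosphorylates site *i* and phosphatase ``Pi`` dephosphorylates site *i*.
Ordered networks use the single-partial-form chain ``A -> Ap -> App`` where the
dephosphorylation order is the reverse of phosphorylation.

Arrow labels are canonical strings and are the keys of every parameter file:
``p:<from>><to>`` for a phosphorylation, ``d:<from>><to>`` for a distributive
dephosphorylation, and ``proc:A11>A00:via01`` / ``proc:A11>A00:via10`` for the
two channels of a processive dephosphorylation (channel = site removed first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ConfigurationError",
    "Topology",
    "EnzymeMode",
    "Dephosphorylation",
    "NetworkSpec",
    "RateTriplet",
    "Totals",
    "ParameterSet",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "symbol_map",
    "catalogue",
]


class ConfigurationError(ValueError):
    """An invalid network specification or mismatched parameter set."""


class Topology(str, Enum):
    single_site = "single_site"
    ordered_dsp = "ordered_dsp"
    random_dsp = "random_dsp"
    ordered_tsp = "ordered_tsp"
    square = "square"


class EnzymeMode(str, Enum):
    common = "common"
    separate = "separate"


class Dephosphorylation(str, Enum):
    distributive = "distributive"
    processive = "processive"


@dataclass(frozen=True)
class NetworkSpec:
    """Which network is being analysed: topology x enzyme sharing x mechanism."""

    topology: Topology
    kinase_mode: EnzymeMode = EnzymeMode.common
    phosphatase_mode: EnzymeMode = EnzymeMode.common
    dephosphorylation: Dephosphorylation = Dephosphorylation.distributive

    def __post_init__(self):
        object.__setattr__(self, "topology", Topology(self.topology))
        object.__setattr__(self, "kinase_mode", EnzymeMode(self.kinase_mode))
        object.__setattr__(self, "phosphatase_mode", EnzymeMode(self.phosphatase_mode))
        object.__setattr__(
            self, "dephosphorylation", Dephosphorylation(self.dephosphorylation)
        )
        self._validate()

    def _validate(self) -> None:
        t, d = self.topology, self.dephosphorylation
        if d is Dephosphorylation.processive:
            if self.phosphatase_mode is not EnzymeMode.common:
                raise ConfigurationError(
                    "processive dephosphorylation requires phosphatase_mode='common' "
                    "(one phosphatase performs both demodifications)"
                )
            if t is not Topology.random_dsp:
                raise ConfigurationError(
                    "processive dephosphorylation is only modelled on the random "
                    "double-site topology"
                )
        if t is Topology.ordered_tsp and (
            self.kinase_mode is not EnzymeMode.common
            or self.phosphatase_mode is not EnzymeMode.common
            or d is not Dephosphorylation.distributive
        ):
            raise ConfigurationError(
                "ordered_tsp is supported only with common kinase, common "
                "phosphatase, distributive dephosphorylation"
            )
        if t is Topology.square and (
            self.kinase_mode is not EnzymeMode.separate
            or self.phosphatase_mode is not EnzymeMode.separate
            or d is not Dephosphorylation.distributive
        ):
            raise ConfigurationError(
                "the square abstraction has one enzyme per arrow: use "
                "kinase_mode='separate', phosphatase_mode='separate', distributive"
            )

    def label(self) -> str:
        return "/".join(
            (
                self.topology.value,
                self.kinase_mode.value,
                self.phosphatase_mode.value,
                self.dephosphorylation.value,
            )
        )


@dataclass(frozen=True)
class RateTriplet:
    """Binding, unbinding and catalytic rate constants of one modification arrow.

    Units: ``k_on`` 1/(concentration*time); ``k_off``, ``k_cat`` 1/time.
    """

    k_on: float
    k_off: float
    k_cat: float

    def __post_init__(self):
        for name in ("k_on", "k_off", "k_cat"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigurationError(f"RateTriplet.{name} must be finite and > 0, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_on, self.k_off, self.k_cat)


@dataclass(frozen=True)
class Totals:
    """Total substrate concentration and total concentration of each enzyme."""

    substrate_total: float
    enzyme_totals: Mapping[str, float]

    def __post_init__(self):
        if not (math.isfinite(self.substrate_total) and self.substrate_total > 0):
            raise ConfigurationError("substrate_total must be finite and > 0")
        for e, v in self.enzyme_totals.items():
            if not (math.isfinite(v) and v > 0):
                raise ConfigurationError(f"enzyme total {e!r} must be finite and > 0, got {v!r}")
        object.__setattr__(self, "enzyme_totals", dict(self.enzyme_totals))

    def with_substrate(self, a_total: float) -> "Totals":
        return Totals(a_total, dict(self.enzyme_totals))


@dataclass(frozen=True)
class ParameterSet:
    """Per-arrow rate triplets plus total concentrations."""

    triplets: Mapping[str, RateTriplet]
    totals: Totals

    def __post_init__(self):
        object.__setattr__(self, "triplets", dict(self.triplets))

    def validate_for(self, network: "ReactionNetwork") -> None:
        have, want = set(self.triplets), set(network.arrows)
        if have != want:
            raise ConfigurationError(
                f"parameter arrows do not match network {network.spec.label()}: "
                f"missing {sorted(want - have)}, unexpected {sorted(have - want)}"
            )
        ehave, ewant = set(self.totals.enzyme_totals), set(network.enzymes)
        if ehave != ewant:
            raise ConfigurationError(
                f"enzyme totals do not match network enzymes: missing "
                f"{sorted(ewant - ehave)}, unexpected {sorted(ehave - ewant)}"
            )

    def replace_totals(self, totals: Totals) -> "ParameterSet":
        return ParameterSet(dict(self.triplets), totals)


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``arrow``/``role`` identify which rate constant applies: role ``bind`` uses
    k_on, ``unbind`` k_off, ``cat`` k_cat of the arrow's triplet.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    arrow: str
    role: str  # "bind" | "unbind" | "cat"


_ROLE_ATTR = {"bind": "k_on", "unbind": "k_off", "cat": "k_cat"}


class ReactionNetwork:
    """Explicit mass-action network: species, elementary reactions, conservation laws."""

    def __init__(
        self,
        spec: NetworkSpec,
        substrate_forms: list[str],
        enzymes: list[str],
        complexes: list[str],
        reactions: list[Reaction],
        arrow_enzyme: dict[str, str],
        complex_substrate: dict[str, str],
        complex_enzyme: dict[str, str],
    ):
        self.spec = spec
        self.substrate_forms = list(substrate_forms)
        self.enzymes = list(enzymes)
        self.complexes = list(complexes)
        self.species = self.substrate_forms + self.enzymes + self.complexes
        self.species_index = {s: i for i, s in enumerate(self.species)}
        self.reactions = list(reactions)
        self.arrows = sorted({r.arrow for r in reactions})
        self.arrow_enzyme = dict(arrow_enzyme)
        self.complex_substrate = dict(complex_substrate)
        self.complex_enzyme = dict(complex_enzyme)
        self.stoich_matrix = self._build_stoich()
        self.conservation_basis = self._build_conservation()
        self._check_invariants()

    # -- construction -----------------------------------------------------
    def _build_stoich(self) -> np.ndarray:
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for s in r.reactants:
                S[self.species_index[s], j] -= 1
            for s in r.products:
                S[self.species_index[s], j] += 1
        return S

    def _build_conservation(self) -> dict[str, np.ndarray]:
        n = len(self.species)
        laws: dict[str, np.ndarray] = {}
        v = np.zeros(n, dtype=np.int64)
        for s in self.substrate_forms:
            v[self.species_index[s]] = 1
        for c in self.complexes:
            v[self.species_index[c]] = 1  # every complex carries one substrate
        laws["substrate"] = v
        for e in self.enzymes:
            w = np.zeros(n, dtype=np.int64)
            w[self.species_index[e]] = 1
            for c in self.complexes:
                if self.complex_enzyme[c] == e:
                    w[self.species_index[c]] = 1
            laws[e] = w
        return laws

    def _check_invariants(self) -> None:
        for name, v in self.conservation_basis.items():
            if np.any(v @ self.stoich_matrix != 0):
                raise AssertionError(f"conservation vector {name!r} not in left null space")
        # each complex must appear in >= 2 reactions (formation and consumption)
        for c in self.complexes:
            i = self.species_index[c]
            if np.count_nonzero(self.stoich_matrix[i]) < 2:
                raise AssertionError(f"complex {c!r} appears in fewer than 2 reactions")

    # -- queries ----------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_conservation_laws(self) -> int:
        return len(self.conservation_basis)

    def rate_constants(self, params: ParameterSet) -> np.ndarray:
        """Per-reaction rate constants in reaction order."""
        params.validate_for(self)
        return np.array(
            [getattr(params.triplets[r.arrow], _ROLE_ATTR[r.role]) for r in self.reactions]
        )

    def to_dict(self) -> dict:
        """JSON-serialisable description (species, reactions, conservation)."""
        return {
            "spec": {
                "topology": self.spec.topology.value,
                "kinase_mode": self.spec.kinase_mode.value,
                "phosphatase_mode": self.spec.phosphatase_mode.value,
                "dephosphorylation": self.spec.dephosphorylation.value,
            },
            "species": list(self.species),
            "substrate_forms": list(self.substrate_forms),
            "enzymes": list(self.enzymes),
            "complexes": list(self.complexes),
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "arrow": r.arrow,
                    "role": r.role,
                }
                for r in self.reactions
            ],
            "conservation": {k: v.tolist() for k, v in self.conservation_basis.items()},
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReactionNetwork {self.spec.label()}: {self.n_species} species, "
            f"{self.n_reactions} reactions, {self.n_conservation_laws} conservation laws>"
        )


# ---------------------------------------------------------------------------
# arrow catalogues per topology

_RANDOM_P_ARROWS = [
    # (label, site modified)
    ("p:A00>A10", 1),
    ("p:A00>A01", 2),
    ("p:A01>A11", 1),
    ("p:A10>A11", 2),
]
_RANDOM_D_ARROWS = [
    ("d:A10>A00", 1),
    ("d:A01>A00", 2),
    ("d:A11>A01", 1),
    ("d:A11>A10", 2),
]


def _arrow_ends(label: str) -> tuple[str, str]:
    body = label.split(":")[1]
    a, b = body.split(">")
    return a, b


class _Builder:
    def __init__(self, spec: NetworkSpec, substrate_forms: list[str]):
        self.spec = spec
        self.substrate_forms = substrate_forms
        self.enzymes: list[str] = []
        self.complexes: list[str] = []
        self.reactions: list[Reaction] = []
        self.arrow_enzyme: dict[str, str] = {}
        self.complex_substrate: dict[str, str] = {}
        self.complex_enzyme: dict[str, str] = {}

    def enzyme(self, name: str) -> str:
        if name not in self.enzymes:
            self.enzymes.append(name)
        return name

    def distributive(self, label: str, enzyme: str) -> None:
        x, y = _arrow_ends(label)
        c = f"{enzyme}.{label}"
        self.complexes.append(c)
        self.complex_substrate[c] = x
        self.complex_enzyme[c] = enzyme
        self.arrow_enzyme[label] = enzyme
        self.reactions += [
            Reaction((enzyme, x), (c,), label, "bind"),
            Reaction((c,), (enzyme, x), label, "unbind"),
            Reaction((c,), (enzyme, y), label, "cat"),
        ]

    def processive_channel(self, label: str, enzyme: str, mid: str) -> None:
        # bound channel A11 -> (bound mid) -> release A00; no partial release
        c1 = f"{enzyme}.{label}.A11"
        c2 = f"{enzyme}.{label}.{mid}"
        self.complexes += [c1, c2]
        self.complex_substrate[c1] = "A11"
        self.complex_substrate[c2] = mid
        self.complex_enzyme[c1] = enzyme
        self.complex_enzyme[c2] = enzyme
        self.arrow_enzyme[label] = enzyme
        self.reactions += [
            Reaction((enzyme, "A11"), (c1,), label, "bind"),
            Reaction((c1,), (enzyme, "A11"), label, "unbind"),
            Reaction((c1,), (c2,), label, "cat"),
            Reaction((c2,), (enzyme, "A00"), label, "cat"),
        ]

    def build(self) -> ReactionNetwork:
        return ReactionNetwork(
            self.spec,
            self.substrate_forms,
            self.enzymes,
            self.complexes,
            self.reactions,
            self.arrow_enzyme,
            self.complex_substrate,
            self.complex_enzyme,
        )


def build_network(spec: NetworkSpec) -> ReactionNetwork:
    """Expand a :class:`NetworkSpec` into its elementary mass-action network."""
    t = spec.topology
    if t is Topology.single_site:
        b = _Builder(spec, ["A", "Ap"])
        b.distributive("p:A>Ap", b.enzyme("K"))
        b.distributive("d:Ap>A", b.enzyme("P"))
        return b.build()

    if t in (Topology.ordered_dsp, Topology.ordered_tsp):
        forms = ["A", "Ap", "App"] if t is Topology.ordered_dsp else ["A", "Ap", "App", "Appp"]
        b = _Builder(spec, forms)
        chain = list(zip(forms[:-1], forms[1:]))
        sep_k = spec.kinase_mode is EnzymeMode.separate
        sep_p = spec.phosphatase_mode is EnzymeMode.separate
        for i, (x, y) in enumerate(chain, start=1):
            b.distributive(f"p:{x}>{y}", b.enzyme(f"K{i}" if sep_k else "K"))
        for i, (x, y) in enumerate(chain, start=1):
            b.distributive(f"d:{y}>{x}", b.enzyme(f"P{i}" if sep_p else "P"))
        return b.build()

    # random double-site topologies (incl. square abstraction, processive variants)
    b = _Builder(spec, ["A00", "A01", "A10", "A11"])
    if t is Topology.square:
        for label, _site in _RANDOM_P_ARROWS + _RANDOM_D_ARROWS:
            b.distributive(label, b.enzyme(f"E[{label}]"))
        return b.build()

    sep_k = spec.kinase_mode is EnzymeMode.separate
    for label, site in _RANDOM_P_ARROWS:
        b.distributive(label, b.enzyme(f"K{site}" if sep_k else "K"))
    if spec.dephosphorylation is Dephosphorylation.processive:
        p = b.enzyme("P")
        b.processive_channel("proc:A11>A00:via01", p, "A01")
        b.processive_channel("proc:A11>A00:via10", p, "A10")
    else:
        sep_p = spec.phosphatase_mode is EnzymeMode.separate
        for label, site in _RANDOM_D_ARROWS:
            b.distributive(label, b.enzyme(f"P{site}" if sep_p else "P"))
    return b.build()


def symbol_map(spec: NetworkSpec) -> dict[str, tuple[str, str]]:
    """Map conventional catalytic-constant symbols to (arrow, role) pairs.

    Random networks: ``k1``/``k2`` are the catalytic constants of
    phosphorylation along the leg A00 -> A01 -> A11, ``a1``/``a2`` along
    A00 -> A10 -> A11; ``k4``/``k3`` are the dephosphorylations A01 -> A00 and
    A11 -> A01 (interconversions on the first leg).  Under Case 2 symmetry the
    two legs are equivalent, so the same symbols also serve the Case 2
    criterion (k1 = phosphorylation of A00, k2 = of the partial forms, k3 =
    dephosphorylation of A11, k4 = of the partial forms).  Ordered networks:
    ``k1``/``k2`` are the first and second phosphorylation.
    """
    t = spec.topology
    if t in (Topology.random_dsp, Topology.square):
        m = {
            "k1": ("p:A00>A01", "cat"),
            "k2": ("p:A01>A11", "cat"),
            "a1": ("p:A00>A10", "cat"),
            "a2": ("p:A10>A11", "cat"),
        }
        if spec.dephosphorylation is Dephosphorylation.distributive:
            m["k4"] = ("d:A01>A00", "cat")
            m["k3"] = ("d:A11>A01", "cat")
        return m
    if t is Topology.ordered_dsp:
        return {"k1": ("p:A>Ap", "cat"), "k2": ("p:Ap>App", "cat")}
    if t is Topology.ordered_tsp:
        return {
            "k1": ("p:A>Ap", "cat"),
            "k2": ("p:Ap>App", "cat"),
            "k3": ("p:App>Appp", "cat"),
        }
    return {"k1": ("p:A>Ap", "cat")}


def catalogue() -> dict[str, NetworkSpec]:
    """The ten studied networks, by short name."""
    T, E, D = Topology, EnzymeMode, Dephosphorylation
    return {
        "random_ckcp": NetworkSpec(T.random_dsp, E.common, E.common, D.distributive),
        "random_skcp": NetworkSpec(T.random_dsp, E.separate, E.common, D.distributive),
        "random_sksp": NetworkSpec(T.random_dsp, E.separate, E.separate, D.distributive),
        "ordered_ckcp": NetworkSpec(T.ordered_dsp, E.common, E.common, D.distributive),
        "ordered_sksp": NetworkSpec(T.ordered_dsp, E.separate, E.separate, D.distributive),
        "mixed1": NetworkSpec(T.random_dsp, E.common, E.common, D.processive),
        "mixed2": NetworkSpec(T.random_dsp, E.separate, E.common, D.processive),
        "ordered_tsp": NetworkSpec(T.ordered_tsp, E.common, E.common, D.distributive),
        "single_site": NetworkSpec(T.single_site, E.separate, E.separate, D.distributive),
        "square": NetworkSpec(T.square, E.separate, E.separate, D.distributive),
    }
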