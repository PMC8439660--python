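"""Minimal SBML Level 3 export/import for the mass-action networks.

Writes an SBML L3V2 core document with one irreversible reaction per
elementary step and a mass-action kinetic law (a single local parameter ``k``
times the reactant concentrations).  The importer reads back exactly what the
exporter writes — enough for round-trip checks and for handing models to
external SBML-aware simulators.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

from .networks import ConfigurationError, ParameterSet, ReactionNetwork

__all__ = ["export_sbml", "parse_sbml", "ParsedSBML"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(name: str) -> str:
    """SBML ids must match [A-Za-z_][A-Za-z0-9_]*."""
    out = []
    for ch in name:
        out.append(ch if ch.isalnum() or ch == "_" else "_")
    s = "".join(out)
    return s if (s and (s[0].isalpha() or s[0] == "_")) else "_" + s


def export_sbml(network: ReactionNetwork, params: ParameterSet) -> str:
    """Serialize a parameterised network as an SBML Level 3 document."""
    params.validate_for(network)
    k = network.rate_constants(params)
    ET.register_namespace("", SBML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model",
                          {"id": _sid(network.spec.label()), "name": network.spec.label()})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true"})
    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    totals = {network.substrate_forms[0]: params.totals.substrate_total}
    totals.update(params.totals.enzyme_totals)
    for s in network.species:
        ET.SubElement(los, f"{{{SBML_NS}}}species", {
            "id": _sid(s), "name": s, "compartment": "cell",
            "initialConcentration": repr(float(totals.get(s, 0.0))),
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "false", "constant": "false",
        })
    lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for j, r in enumerate(network.reactions):
        rx = ET.SubElement(lor, f"{{{SBML_NS}}}reaction", {
            "id": f"r{j}", "name": f"{r.arrow}:{r.role}", "reversible": "false",
        })
        lre = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
        for s in r.reactants:
            ET.SubElement(lre, f"{{{SBML_NS}}}speciesReference",
                          {"species": _sid(s), "stoichiometry": "1", "constant": "true"})
        lpr = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
        for s in r.products:
            ET.SubElement(lpr, f"{{{SBML_NS}}}speciesReference",
                          {"species": _sid(s), "stoichiometry": "1", "constant": "true"})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        apply_ = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply_, f"{{{MATHML_NS}}}times")
        ci_k = ET.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        ci_k.text = " k "
        for s in r.reactants:
            ci = ET.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci.text = f" {_sid(s)} "
        llp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        ET.SubElement(llp, f"{{{SBML_NS}}}localParameter",
                      {"id": "k", "value": repr(float(k[j]))})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


@dataclass
class ParsedSBML:
    species: list[str]  # SBML ids, document order
    reactions: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    initial: dict[str, float]

    def stoich_matrix(self) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, (reac, prod, _k) in enumerate(self.reactions):
            for s in reac:
                S[idx[s], j] -= 1
            for s in prod:
                S[idx[s], j] += 1
        return S

    def rate_constants(self) -> np.ndarray:
        return np.array([k for _, _, k in self.reactions])


def parse_sbml(document: str) -> ParsedSBML:
    """Read back an SBML document produced by :func:`export_sbml`."""
    root = ET.fromstring(document)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ConfigurationError("document contains no SBML model")
    species, initial = [], {}
    for sp in model.iter(f"{{{SBML_NS}}}species"):
        species.append(sp.get("id"))
        initial[sp.get("id")] = float(sp.get("initialConcentration", "0"))
    reactions = []
    for rx in model.iter(f"{{{SBML_NS}}}reaction"):
        reac = tuple(
            sr.get("species")
            for lo in rx.findall(f"{{{SBML_NS}}}listOfReactants")
            for sr in lo.findall(f"{{{SBML_NS}}}speciesReference")
        )
        prod = tuple(
            sr.get("species")
            for lo in rx.findall(f"{{{SBML_NS}}}listOfProducts")
            for sr in lo.findall(f"{{{SBML_NS}}}speciesReference")
        )
        k = None
        for lp in rx.iter(f"{{{SBML_NS}}}localParameter"):
            if lp.get("id") == "k":
                k = float(lp.get("value"))
        if k is None:
            raise ConfigurationError(f"reaction {rx.get('id')} has no rate constant")
        reactions.append((reac, prod, k))
    return ParsedSBML(species, reactions, initial)
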