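"""Configuration, serialization and tabular output.

JSON is the canonical on-disk format; YAML is accepted for human-written
configs.  Numbers are serialized with 17 significant digits so that any
artifact is regenerable bit-identically from its config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .networks import (
    ConfigurationError,
    NetworkSpec,
    ParameterSet,
    RateTriplet,
    ReactionNetwork,
    Totals,
    build_network,
)

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "params_to_dict",
    "params_from_dict",
    "read_config",
    "write_config",
    "write_branch_csv",
    "write_trajectory_csv",
]


def spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "topology": spec.topology.value,
        "kinase_mode": spec.kinase_mode.value,
        "phosphatase_mode": spec.phosphatase_mode.value,
        "dephosphorylation": spec.dephosphorylation.value,
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    allowed = {"topology", "kinase_mode", "phosphatase_mode", "dephosphorylation"}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown network keys: {sorted(unknown)}")
    if "topology" not in d:
        raise ConfigurationError("network.topology is required")
    try:
        return NetworkSpec(**d)
    except ValueError as e:
        raise ConfigurationError(str(e)) from e


def params_to_dict(params: ParameterSet) -> dict:
    return {
        "triplets": {
            a: {"k_on": t.k_on, "k_off": t.k_off, "k_cat": t.k_cat}
            for a, t in sorted(params.triplets.items())
        },
        "totals": {
            "substrate_total": params.totals.substrate_total,
            "enzyme_totals": dict(sorted(params.totals.enzyme_totals.items())),
        },
    }


def params_from_dict(d: dict, network: ReactionNetwork | None = None) -> ParameterSet:
    try:
        triplets = {}
        for a, t in d["triplets"].items():
            if isinstance(t, (list, tuple)):
                triplets[a] = RateTriplet(*t)
            else:
                triplets[a] = RateTriplet(t["k_on"], t["k_off"], t["k_cat"])
        tot = d["totals"]
        params = ParameterSet(
            triplets, Totals(tot["substrate_total"], tot["enzyme_totals"])
        )
    except KeyError as e:
        raise ConfigurationError(f"missing parameter field: {e}") from e
    except TypeError as e:
        raise ConfigurationError(f"malformed parameter entry: {e}") from e
    if network is not None:
        params.validate_for(network)
    return params


def _load(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


DEFAULT_OPTIONS = {
    "rtol": 1e-8,
    "n_starts": 64,
    "seed": 0,
    "settle_fraction": 0.5,
}


def read_config(path) -> tuple[NetworkSpec, ParameterSet, dict]:
    """Read and validate a (network, parameters, options) configuration."""
    d = _load(path)
    if "network" not in d or "parameters" not in d:
        raise ConfigurationError("config must contain 'network' and 'parameters'")
    spec = spec_from_dict(d["network"])
    network = build_network(spec)
    params = params_from_dict(d["parameters"], network)
    options = dict(DEFAULT_OPTIONS)
    options.update(d.get("options", {}))
    return spec, params, options


def write_config(path, spec: NetworkSpec, params: ParameterSet, options: dict | None = None):
    d = {"network": spec_to_dict(spec), "parameters": params_to_dict(params)}
    if options:
        d["options"] = dict(sorted(options.items()))
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_branch_csv(branch, path, branch_id: int = 0) -> None:
    """Branch table: A_Total, every species in catalogue order, stability, id.

    Bifurcation points are appended as a sidecar ``<path>.bifurcations.json``.
    """
    if len(branch.points) == 0:
        raise ValueError("cannot write an empty branch")
    net = branch.network
    path = Path(path)
    with path.open("w") as fh:
        fh.write("A_Total," + ",".join(net.species) + ",stability,branch_id\n")
        for pt in branch.points:
            fh.write(
                ",".join([_fmt(pt.a_total)] + [_fmt(v) for v in pt.x])
                + f",{pt.stability},{branch_id}\n"
            )
    side = {
        "bifurcations": [
            {
                "kind": bp.kind,
                "A_Total": bp.a_total,
                "classification": bp.classification,
                "state": [float(v) for v in bp.x],
            }
            for bp in branch.bifurcations
        ]
    }
    path.with_suffix(path.suffix + ".bifurcations.json").write_text(
        json.dumps(side, indent=2) + "\n"
    )


def write_trajectory_csv(traj, path) -> None:
    net = traj.network
    with Path(path).open("w") as fh:
        fh.write("time," + ",".join(net.species) + "\n")
        for t, x in zip(traj.times, traj.states):
            fh.write(",".join([_fmt(t)] + [_fmt(v) for v in x]) + "\n")
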