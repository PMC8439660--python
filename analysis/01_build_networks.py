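"""Catalogue the studied phosphorylation networks as mass-action systems.

Builds each network of the catalogue, records its size (species, elementary
reactions, conservation laws), verifies the conservation structure, and writes
the table to results/network_catalogue.csv plus one example SBML export.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from symphos.networks import build_network, catalogue
from symphos.paramgen import sample_params
from symphos.sbml import export_sbml

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

rows = []
for name, spec in catalogue().items():
    net = build_network(spec)
    for v in net.conservation_basis.values():
        assert np.all(v @ net.stoich_matrix == 0)
    rows.append({
        "network": name,
        "topology": spec.topology.value,
        "kinase": spec.kinase_mode.value,
        "phosphatase": spec.phosphatase_mode.value,
        "dephosphorylation": spec.dephosphorylation.value,
        "species": net.n_species,
        "reactions": net.n_reactions,
        "conservation_laws": net.n_conservation_laws,
    })

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "network_catalogue.csv", index=False)
print(df.to_string(index=False))

spec = catalogue()["ordered_ckcp"]
doc = export_sbml(build_network(spec), sample_params(spec, 0))
(RESULTS / "ordered_ckcp.sbml.xml").write_text(doc)
print(f"\nwrote {RESULTS/'network_catalogue.csv'} and an example SBML export; "
      "every conservation vector is an exact integer left null vector.")
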