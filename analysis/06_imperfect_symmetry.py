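"""Echoes of symmetry breaking off the exactly symmetric manifold.

Perturbs the frozen ordered parameter set multiplicatively by eps, continues
the connected branch through the unfolded (imperfect) pitchfork, and measures
how far the formerly pinned partial phosphoform drifts: the deviation shrinks
with eps, so near-symmetric networks retain approximate robustness.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from symphos.continuation import ContinuationOptions, continue_branch
from symphos.paramgen import perturb_symmetry, regime_library
from symphos.steady import solve_steady
from symphos.symmetry import involution_for

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

fx = regime_library()["ordered_case1"]
inv = involution_for(fx.spec, fx.case)
net = inv.network
opts = ContinuationOptions(ds0_rel=1e-3, ds_max_rel=2e-3)
rows = []
for eps in (1e-2, 1e-3, 1e-4):
    p = perturb_symmetry(fx.params, inv, eps, seed=2)
    p0 = p.replace_totals(p.totals.with_substrate(0.5))
    x0 = np.zeros(net.n_species)
    x0[net.species_index["A"]] = 0.5
    for e in net.enzymes:
        x0[net.species_index[e]] = p0.totals.enzyme_totals[e]
    br = continue_branch(net, p0, (0.5, 30.0), solve_steady(net, p0, x0).x,
                         involution=inv, enforce_symmetry=False, options=opts)
    n_pf = len([b for b in br.bifurcations if b.kind == "pitchfork"])
    ap = br.species_values("Ap")
    sel = br.a_values > 15.0
    dev = float(np.max(np.abs(ap[sel] - 3.0)) / 3.0)
    rows.append({"epsilon": eps, "pitchforks_on_connected_branch": n_pf,
                 "max_residual": br.max_state_residual(),
                 "ap_deviation_past_bifurcation": dev})
    print(f"eps={eps:g}: connected branch, {n_pf} pitchfork events, "
          f"[Ap] deviation from 3.0 past the former bifurcation: {dev:.3e}")

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "imperfect_symmetry.csv", index=False)
assert df.ap_deviation_past_bifurcation.is_monotonic_decreasing
print(f"deviation decreases monotonically as eps -> 0; "
      f"wrote {RESULTS/'imperfect_symmetry.csv'}")
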