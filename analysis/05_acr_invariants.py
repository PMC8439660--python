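"""Concentration robustness of the symmetry-broken states.

Reproduces the invariant table — which species (or sums) are pinned on the
asymmetric branches of each network/symmetry combination — then maps the
origins of the robustness in a *non-symmetric* ordered network (two robust
branches crossing a third in a transcritical point, robustness only against
total substrate), and constructs approximate robustness in limiting kinetic
regimes without any multistability.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from symphos.continuation import switch_branch
from symphos.criteria import numeric_breaking_test
from symphos.networks import build_network, catalogue
from symphos.paramgen import regime_library
from symphos.robustness import (
    approx_acr_params,
    discover_invariants,
    transcritical_acr_scan,
)
from symphos.symmetry import involution_for

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
lib = regime_library()
rows = []

for name in ("ordered_case1", "random_ckcp_case1", "sksp_case1", "sksp_case2",
             "case3_ckcp_super", "case3_sksp_super", "mixed2_case2", "tsp_shared"):
    fx = lib[name]
    inv = involution_for(fx.spec, fx.case)
    rep = numeric_breaking_test(fx.spec, fx.params, inv=inv, a_range=fx.a_range)
    pf = [b for b in rep.branch.bifurcations if b.kind == "pitchfork"][0]
    b1 = switch_branch(inv.network, fx.params, pf, +1, fx.a_range, inv)
    b2 = switch_branch(inv.network, fx.params, pf, -1, fx.a_range, inv)
    found = discover_invariants([b1, b2], tol=1e-6)
    shared = ["+".join(t) if isinstance(t, tuple) else t
              for t, hits, _ in found if len(hits) == 2]
    rows.append({"fixture": name, "exact_invariants": ";".join(shared) or "(none)"})
    print(f"{name:22s} exact invariants on asymmetric branches: {shared or 'none'}")

# non-symmetric origins of the robustness
fx = lib["ordered_acr_nonsym"]
net = build_network(fx.spec)
rep = transcritical_acr_scan(net, fx.params, fx.a_range, seed=0)
flat = [v for v, f in zip(rep.acr_values, rep.acr_flags) if f]
tcs = [e["a_total"] for e in rep.intersections if e["kind"] == "transcritical"]
print(f"\nnon-symmetric ordered network: {len(flat)} branches with [Ap] pinned at "
      f"{np.mean(flat):.6f}; transcritical crossing at A_Total = {tcs[0]:.4f}; "
      f"robust against enzyme totals: {rep.robust_vs_enzyme_totals}")
rows.append({"fixture": "ordered_acr_nonsym",
             "exact_invariants": f"Ap={np.mean(flat):.6f} on {len(flat)} branches"})

# approximate robustness from limiting regimes, no multistability involved
for target in ("App", "Ap", "A"):
    _, dev, reached = approx_acr_params(catalogue()["ordered_ckcp"], target, seed=1)
    print(f"limiting-regime approximate robustness of {target}: "
          f"deviation {dev:.2%} over a twofold A_Total window (reached: {reached})")
    rows.append({"fixture": f"approx_acr_{target}",
                 "exact_invariants": f"deviation {dev:.4f}"})

pd.DataFrame(rows).to_csv(RESULTS / "acr_invariants.csv", index=False)
print(f"wrote {RESULTS/'acr_invariants.csv'}")
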