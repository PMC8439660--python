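# symphos

Symmetry and symmetry breaking in multisite phosphorylation networks.

Reversible multisite modification of a substrate by kinases and phosphatases
is one of the basic information-processing units of cell signalling.  When
the modification network carries a symmetry — equal kinetics for the two
modification directions (`[A00] = [A11]`, Case 1), for the two modification
legs (`[A01] = [A10]`, Case 2), or both at once along the diagonal (Case 3) —
that symmetry can *break* spontaneously as the total substrate concentration
A_Total grows, purely through enzyme sequestration, with no explicit feedback.
The symmetric steady state loses stability at a pitchfork bifurcation to a
pair of mirror-image asymmetric states, and on those asymmetric branches
specific species are pinned exactly at their bifurcation values: absolute
concentration robustness (ACR) against A_Total.

This package implements that analysis end to end for the family of
double/triple-site networks with common or separate converter enzymes:

* **`symphos.networks`** — mass-action models built from elementary
  binding/unbinding/catalysis steps, with exact integer conservation laws;
* **`symphos.symmetry`** — the three symmetry classes as involutions
  (species permutation + enzyme pairing + arrow pairing), derived rather than
  hard-coded, so the structural impossibilities (e.g. Case 1 with separate
  kinases but a common phosphatase) emerge from the construction;
* **`symphos.dynamics` / `symphos.steady`** — reduced stiff dynamics,
  damped-Newton steady states, and a multistart sweep (Newton +
  pseudo-transient continuation) used as the numerical oracle;
* **`symphos.continuation`** — pseudo-arclength continuation in A_Total with
  symmetry-adapted detection of pitchfork, Hopf, fold and transcritical
  points, branch switching and pitchfork classification;
* **`symphos.criteria`** — the analytic breaking criteria per network and
  case (e.g. `k2 > k1` for the ordered chain;
  `k1/k4 > PT/KT > k2/k3` for Case 2 with separate enzymes), each
  cross-checked against the continuation oracle;
* **`symphos.robustness`** — exact and approximate ACR on branches, blind
  invariant discovery, the transcritical origin of ACR in non-symmetric
  networks, and saturated/unsaturated limiting regimes giving approximate
  robustness without multistability;
* **`symphos.paramgen`** — seeded log-uniform parameter generators,
  criterion-conditioned symmetric sampling, epsilon-perturbations off
  symmetry, and the frozen fixture library.

The numbered scripts under `analysis/` run the study: network catalogue,
ordered-chain pitchfork and Ap pinning, criterion/oracle concordance, Case 3
bifurcation structure and oscillations, the ACR invariant table, and
imperfect-symmetry unfolding.  Each writes its table under `results/`.

## Worked example

The ordered double-site chain `A -> Ap -> App` with common kinase and
phosphatase, symmetric rates (all binding/unbinding constants 1, first
phosphorylation/last dephosphorylation k_cat 1, second phosphorylation/first
dephosphorylation k_cat 2, K_Total = P_Total = 1):

```sh
python analysis/02_ordered_pitchfork.py
```

prints

```
symmetric branch: 30 points over A_Total in [0.5, 30.0]
pitchfork at A_Total = 12.500000 (analytic value 12.5 for this parameter set)
classification: supercritical
[Ap] at the bifurcation: 3.000000 (= KM2 k1/(k2 - k1) = 3 for this set)
max relative deviation of [Ap] along both asymmetric branches: 1.056e-09
```

Because k2 > k1, the no-bias steady state (`[A] = [App]`, equal free enzymes)
destabilizes at A_Total = 12.5 through a supercritical pitchfork; beyond it
the system picks a modification direction, and on both asymmetric branches
the partial phosphoform stays pinned at [Ap] = 3 while A_Total more than
doubles — exact concentration robustness born at the bifurcation.  The same
library calls drive all other regimes (subcritical pitchforks with
tristability, Hopf points with period-lengthening oscillations, processive
networks, triple-site shared robustness).

The CLI wraps the common operations, e.g.

```sh
symphos gen-params --network ordered_ckcp --case case1 --condition satisfy \
        --seed 1 --out cfg.json
symphos continue --config cfg.json --range 0.5:30 --case case1 --out branch.csv
symphos criteria --config cfg.json
```

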