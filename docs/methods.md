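# Methods

## Model class

Every network is a pure mass-action system built from the elementary
description of a single enzymatic conversion: reversible complex formation
followed by irreversible catalysis,

    E + X  <->[k_on, k_off]  E·X  ->[k_cat]  E + Y.

No Michaelis–Menten or quasi-steady-state reduction is applied anywhere: the
only nonlinearity in the models is enzyme sequestration in complexes, which is
exactly the ingredient responsible for symmetry breaking in this network
family.  The catalogue covers random and ordered double-site phosphorylation
with common or separate kinases/phosphatases, a processive-dephosphorylation
variant, an ordered triple-site chain, single-site modification, and the
"square" abstraction with one enzyme per arrow.

Site convention: substrate subscripts index sites with the leftmost digit
first (`A10` = site 1 modified).  In separate-enzyme networks `Ki`
phosphorylates site *i* and `Pi` dephosphorylates site *i*.  This convention
fixes the enzyme pairing under the symmetries below; where the literature's
subscripting is ambiguous, the pairing was validated numerically (see
"Case 1 criterion with separate enzymes").

Processive dephosphorylation is modelled as two *bound channels* with no
intermediate release: each channel (site removed first) has its own
bound-`A11` complex, parameterised by an independent (k_on, k_off, k_cat)
triplet, and both catalytic steps of a channel share its k_cat.  A single
shared bound-`A11` complex cannot carry two independent binding/unbinding
pairs, and the two-complex form keeps the leg-exchange involution exact for
any channel-symmetric parameters.

Units are arbitrary (concentration, time); all rate constants are positive
finite reals.

## Symmetries as involutions

Each symmetry class is represented by an involution: a species permutation, an
enzyme pairing, and an arrow pairing.  The involution is *derived*: given the
substrate permutation of the case (direction exchange `A00<->A11`, leg
exchange `A01<->A10`, or their composition), the image of every arrow is
computed and matched against the network's arrow set, and the induced enzyme
pairing must itself be a bijective involution.  The structural impossibility
results (direction and diagonal symmetry in the separate-kinase
common-phosphatase network; any two-partial-form symmetry on ordered
topologies) fall out of this construction rather than being special-cased: the
induced enzyme map fails to be an involution, or an arrow has no image.

Parameter-space projection (`symmetrize`) replaces paired constants and paired
enzyme totals by componentwise *geometric* means: rate constants are scale
parameters, the geometric mean preserves positivity, and the projection is
idempotent.  Symmetry residuals are maximal absolute log-ratios over pairs;
state residuals are maximal coordinate differences from the permuted state,
relative to the substrate pool.

## Reduction and steady states

One species per conservation law is eliminated — the unmodified substrate form
and every free enzyme — keeping the modified forms, which carry the
robustness invariants, as explicit coordinates.  Time integration (LSODA with
the analytic Jacobian) runs in reduced coordinates, so conserved totals are
held exactly.

Steady states are found by damped Newton on the reduced system with an extra
full-step polish down to the machine floor (sharp states are needed for the
sweep's deduplication at relative 1e-6).  The multistart sweep draws
admissible starts (Dirichlet split of the substrate pool over the substrate
forms, enzymes free) and runs *two* solvers from each start: plain Newton,
which reaches unstable states, and pseudo-transient continuation (an
implicit-Euler-like damping that follows the flow), which reliably reaches the
stable attractor of the start's basin.  Plain Newton alone almost never finds
the asymmetric attractors — its basins are fractal and biased toward the
symmetric state — which is why the flow-following stage exists.  Stability is
classified from reduced-Jacobian eigenvalues with threshold 1e-8 times the
characteristic rate (largest first-order rate constant, with binding scaled by
the largest total).

## Continuation and bifurcation detection

Branches of steady states are traced in the total substrate concentration
A_Total with a tangent (Keller) predictor and bordered Newton corrector.
Numerical choices:

* step size adapts between 1e-7 and 5e-2 of the requested range, *and* is
  capped at 0.25 x the local concentration scale max(A_Total, enzyme totals) —
  wide scans are therefore traversed geometrically and cannot skip over
  structure;
* corrector solutions with concentrations below -1e-6 x scale are rejected,
  so branches cannot silently jump onto unphysical solution sheets;
* on symmetry-invariant branches every corrector iterate is projected back
  onto the (A_Total-dependent, affine) symmetric manifold, so roundoff cannot
  leak onto emanating asymmetric branches and the antisymmetric test stays
  exact.

Test functions, evaluated at every accepted point and bisected to a relative
1e-8 in A_Total on a sign change:

* **pitchfork** — the signed n-th root of det of the Jacobian restricted to
  the antisymmetric eigenspace of the involution.  The determinant flips sign
  exactly when a real antisymmetric eigenvalue crosses zero; a leading-real-
  eigenvalue test was tried first and produced spurious events whenever a
  complex antisymmetric pair turned real away from the axis.
* **Hopf** — largest real part over complex eigenvalue pairs, with the refined
  point validated to carry a pair *on* the axis (imaginary part above
  tolerance, real part below 1e-3 x characteristic rate); this filters the
  jumps caused by real pairs merging into complex ones.
* **fold** — sign change of dA_Total/ds of the bordered-system tangent,
  refined by arclength bisection with mid-point correctors.
* **transcritical** — on non-symmetric scans, a det(J) sign change with no
  accompanying fold.

Branch switching at a pitchfork prescribes the *antisymmetric amplitude* and
leaves A_Total free: the amplitude is the linear functional measuring distance
from the A_Total-dependent symmetric manifold along the critical eigenvector
(the involution's eigenspaces are not orthogonal and the manifold drifts with
A_Total, so a naive inner product with the eigenvector is satisfiable by
sliding along the symmetric branch — both failure modes were observed and are
excluded by construction).  A single pseudo-arclength run then follows the
emanating branch, backwards through the stabilizing fold when the pitchfork is
subcritical.  Classification (super/subcritical) is decided by the side of the
pitchfork on which the branches emanate relative to the side on which the
symmetric state is antisymmetrically unstable, with stability at inception as
a tie-break.

## Breaking criteria

The analytic inequalities are transcribed in terms of catalytic constants via
a fixed symbol map (`k1`, `k2` along the leg through `A01`; `a1`, `a2` along
the leg through `A10`; `k3`, `k4` the first-leg dephosphorylations).  The
signed criteria for the common-enzyme random network contain positive
constants (alpha, c1, c3) that depend on the remaining kinetics; their closed
forms are not transcribed, so these criteria are evaluated only in regimes
where the sign is constant-free (both terms agreeing), and raise otherwise,
deferring to the numeric oracle.  All inequalities are strict; equality is the
degenerate boundary and counts as non-breaking.

`numeric_breaking_test` is the ground truth: it continues the symmetric branch
over a scan range (default 1e-2 to 1e3 times the largest enzyme total) and
reports whether the antisymmetric test function crosses zero.  A negative
verdict is conclusive only up to the cap: "breaking for *some* total
substrate" can in principle exceed any finite scan, and concordance runs log
such cases (observed at the few-percent level in conditioned ensembles).

**Case 1 criterion with separate enzymes.**  The inequality pair couples the
catalytic ratios of the two legs to the ratio of phosphatase totals; which
phosphatase total belongs in which inequality depends on the subscripting
convention.  Both orientations were scored against the numeric oracle on 60
seeded symmetric parameter sets: the implemented orientation
(k2/k1 > P1T/P2T and a2/a1 > P2T/P1T under this package's site convention)
gave no false positives and no false negatives; the mirrored orientation
failed both ways.  The criterion is documented accordingly.

## Concentration robustness

`acr_deviation` measures the maximal relative deviation of a species or
pair-sum from its value at the branch's inception bifurcation.  Exact
invariance uses tolerance 1e-6 (relative); approximate robustness targets < 5%
over a twofold A_Total window.  Both are configurable.  `discover_invariants`
scans single substrate forms and unordered pairwise sums only — all known
invariants of these networks live on the substrate forms, and excluding
complexes bounds the scan.

The origin scan (`transcritical_acr_scan`) makes no symmetry assumption: all
branches reachable by multistart seeding over a coarse A_Total grid are
continued (both tangent directions, deduplicated by interpolated-state
coverage), each is tested for flatness of the partial phosphoform, crossings
are collected from the det-based test, and the flat level is re-measured under
perturbed kinase/phosphatase totals (x1.2) to verify that the robustness
holds only against total substrate.  For the non-symmetric fixture the
parameters are constructed, not searched: eliminating complexes from the
steady-state conditions of the ordered chain shows that a branch family with
the partial form pinned exists exactly when two rational expressions in the
rate constants and totals agree — a single scalar constraint, strictly weaker
than symmetry, which reduces to the k2 > k1 threshold in the symmetric case.
The fixture's second-phosphorylation k_cat solves that constraint in closed
form, and the resulting pinned level (2.66299...) is then *recovered*
numerically by the scan.

Approximate robustness without multistability is constructed from limiting
kinetic regimes: the enzyme step producing the target runs in deep saturation
(Michaelis constant ~5e-3 against order-10 substrate), so its flux is set by
its enzyme total alone; consumption of the target is unsaturated with the
opposing enzyme in excess; competing drains of the saturated step's substrate
are weakened so saturation is not starved.  For interior forms only the
kinase-side producer is saturated.  Measured deviations are ~0.2% or less over
a twofold window, with the sweep confirming a unique steady state throughout.

## Synthetic parameters and fixtures

Generators are pure functions of their seed.  Rate constants are sampled
log-uniformly over three decades ([0.1, 100]) and totals over two
([0.1, 10]): rate constants are scale parameters and the study spans the
saturated-to-unsaturated range around order-one concentrations.  Conditioned
sampling ("satisfy"/"violate") rescales catalytic constants pairwise — so
exact symmetry is preserved — into the regime where the relevant criterion
holds or is precluded, restricted to the constant-free sign regimes for the
signed criteria.  Symmetry perturbations multiply the two sides of each pair
by exp(+-eps*u), u ~ U(0,1), giving residual at most 2 eps.

The regime library is a set of frozen JSON fixtures, each found once by
seeded search during development and committed, covering: the ordered
direction-breaking chain (hand-built round numbers: unit binding/unbinding,
k1 = 1, k2 = 2, equal unit enzyme totals — pitchfork at exactly A_Total =
12.5 with the partial form pinned at KM2·k1/(k2-k1) = 3); conditioned
supercritical pitchforks for the random networks; the subcritical lip with
folds and tristability (found in the mixed-criterion regime k3/k2 > 1,
k1/k4 < 1 — conditioned sampling in the constant-free regime produced only
supercritical, forward-emanating pitchforks across hundreds of draws); two
oscillatory regimes with Hopf points; the processive-network breaking case;
the triple-site chain with shared robustness of the partial-form sum; and the
non-symmetric robustness construction above.  Frozen fixtures make every
bifurcation-structure test reproducible without re-searching.

### What the synthetic data does and does not emulate

The generator reproduces the *structural* conditions of the study — exact
symmetry constraints, criterion regimes, epsilon-perturbations — under
log-uniform kinetics.  It does not emulate measured kinetic constants of any
specific kinase/phosphatase system, crowding or compartment effects,
stochasticity, or upstream/downstream coupling (retroactivity, feedback).
Passing tests therefore establish the claimed behaviour of the mass-action
network class over wide generic parameter regimes, not quantitative agreement
with any particular cellular system.

## Problem sizes

Ensemble sizes used by the test suite and the acceptance script (chosen so
the complete analysis re-runs comfortably on one CPU): 100-set ensembles with
3-start sweeps over 20-point substrate grids for the necessity/impossibility
checks, 200-set ensembles for the structural negative controls, 30-50 sets
for criterion/oracle concordance, and simulations of 3500 time units for
oscillation periods.  The continuation scan cap is 1e3 x the largest enzyme
total throughout.

## Known limitations

* The positive constants of the two signed criteria are not transcribed; in
  mixed-sign regimes only the numeric oracle decides.
* The multistart sweep is probabilistic: uniqueness claims are "no second
  state found at this start count", not algebraic solution counts.
* Oscillations are characterised by simulation (peak detection on the
  post-transient tail); periodic orbits are not continued, so oscillation
  boundaries other than the Hopf point are not localized.
* The numeric breaking test scans a finite substrate range; existence results
  "for some A_Total" beyond the cap register as non-breaking and are logged.
* Two-parameter (codimension-2) continuation is out of scope; regime maps in
  enzyme-total planes are only sampled pointwise.
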