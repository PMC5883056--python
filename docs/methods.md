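# Methods

This note documents the models and procedures implemented in `gxqsar`, the
choices made where the underlying conventions were genuinely open, and what
the synthetic-data generators do and do not emulate.

## Molecular graphs

All descriptors operate on hydrogen-suppressed graphs: heavy atoms with
per-atom hydrogen counts, discrete bond orders, and an all-pairs
shortest-path (bond count) distance matrix. RDKit performs SMILES/SDF
parsing, sanitization, aromaticity perception and Kekulization; the
descriptor mathematics is implemented in this package and regression-tested
against brute-force oracles (breadth-first-search and Floyd–Warshall
distances, exhaustive pair enumeration, O(n²) perturbation loops) kept in
the test tree and never imported by the library.

Aromatic systems are Kekulized deterministically (RDKit's canonical
assignment) before E-state atom typing, and Kekulé double bonds count as
double for the "double-bonded atom" pair class. The alternative — treating
aromatic bonds as a separate class — changes which atoms match types such
as dsCH; the Kekulé convention was chosen because the pair descriptors and
type counts need a discrete bond order, and it is applied uniformly to all
inputs. Multi-fragment inputs are accepted; cross-fragment distances are
infinite and cross-fragment pairs never contribute to pair counts.

## E-state descriptors

The electrotopological state of atom *i* is the standard Kier–Hall
formulation: valence delta δv = Zv − h for second-row atoms and
(Zv − h)/(Z − Zv − 1) for higher rows; intrinsic state
I = ((2/N)²·δv + 1)/δ; perturbation ΔI_i = Σ_j (I_i − I_j)/(d_ij + 1)²
with topological distance damping; S = I + ΔI. The pairwise terms are
antisymmetric, so Σ ΔI = 0 for every molecule — a property the test suite
checks on fixtures and on 1,000 random graphs. Group indices
(SdsCHE-index, SdssCE-index, SssssCE-index) sum S over atoms of the named
environment and are 0.0 when no atom matches; SssssCcount is a pure count.
An isolated heavy atom (δ = 0) has no defined intrinsic state; by default
it is flagged undefined and excluded from the perturbation sums, with an
opt-in `unit-delta` policy that evaluates it as if δ = 1.

`DeltaEpsilonC` is defined here as the spread (max − min) of the Kier–Hall
relative electronegativity ε = (δv − δ)/N² over carbon atoms, 0.0 with
fewer than two carbons. The name originates in proprietary descriptor
software whose exact formula is not public; this carbon-restricted spread
is the package's documented stand-in, versioned and isolated behind a
single function so it can be revised without touching anything else.

`MMFF_29` counts hydrogens of MMFF94 type 29 (enolic/phenolic O–H
hydrogens). Typing delegates to RDKit's MMFF94 implementation over the
hydrogen-expanded molecule; the numeric-to-symbolic type table ships as
package data so the mapping is auditable, and unparameterizable atoms are
reported as `untyped`, never silently dropped. The hydrogen-bond acceptor
rule set (include N/O; exclude positively charged N/O, amide N,
pyrrole-type aromatic N) also ships as a SMARTS data file so it can be
tuned without code changes. Rule-of-five properties use the Lipinski
conventions (HBD = N–H plus O–H hydrogens, HBA = N plus O count) with MW
and logP delegated to RDKit; logP is never reimplemented.

## Dataset handling and splitting

Activities load as IC₅₀ in µM and are transformed to log₁₀ µM at load time
(both columns kept). Rows with missing descriptor values are excluded with
a logged count, never imputed. Correlation pruning is greedy: the most
correlated offending pair above the cutoff is resolved by dropping the
member less correlated with activity (ties drop the higher column index),
zero-variance columns going first.

Sphere exclusion uses the activity-ordered variant: descriptors are
z-standardized, compounds are visited in decreasing activity order (a
seeded shuffle breaks exact ties only), each unassigned visit becomes a
training point, and every unassigned compound within the Euclidean radius
of it is assigned to the test set. Radius 0 therefore yields an all-train
split, and a radius exceeding the data diameter yields a single training
compound. A bisection helper finds the radius for a target train fraction
(default 0.8). Train-set mean/sd per descriptor are stored with the split.
"UniColumn" statistics report per-set mean/max/min/sd for activity and all
descriptors; the coverage verdict is "covered" iff the test activity range
lies within the train range (inclusive).

## Regression and model selection

The inner solver is ordinary least squares with an intercept, solved by
QR; rank deficiency raises an error naming the collinear columns (located
by column-pivoted QR) rather than returning a pseudo-inverse fit. Stepwise
selection is forward-only: each round admits the candidate with the
largest partial F, subject to F ≥ `f_to_enter` (default 4.0, roughly the
5% point of F(1, large)) and |r| ≤ `corr_cutoff` (default 0.7) against
already-selected descriptors; the term cap defaults to n/6, a common
observations-per-parameter heuristic. All three are configurable. There is
no backward elimination. An empty first round returns an intercept-only
model with an explicit warning.

The three published cell-line models ship as JSON data (not code
constants) with their printed coefficients; a test pins every value. They
carry no training ranges, so their applicability-domain flag is reported
as `unavailable` — never a silent 0. For models built here, the AD flag is
0 iff every descriptor lies within the training [min, max] inclusive.
Published equations are assumed to be on raw descriptor scales, since no
standardization parameters are published alongside them.

## Validation battery

* r² = 1 − SSres/SStot on the training fit.
* q² (leave-one-out) via the hat matrix: PRESS = Σ(e_i/(1 − h_ii))²; this
  is algebraically identical to n explicit refits and the suite enforces
  agreement to 1e−10. A leverage of 1 raises an influential-point error
  naming the row.
* pred_r² = 1 − Σ(y_test − ŷ)²/Σ(y_test − ȳ_train)², referenced to the
  training mean.
* rm² metrics (penalized correlation with/without intercept): computed in
  both axis orders with the through-origin slope fit; reported as average
  and absolute delta.
* F = (SSreg/k)/(SSres/(n−k−1)); a perfect fit reports +∞ with a flag.
* Standard errors: RMSE of the fitted, LOO and external residual sets with
  denominators n−k−1, n and n_test.
* Y-randomization: the response is permuted `n_trials` times (default 100,
  seeded) and the full model-building pipeline — including stepwise
  selection when the model was built here — reruns each trial. Reported:
  best random r²/q², Z-scores for both (the q²-based one labeled primary,
  since either could legitimately headline a report), and
  alpha = (#{random r² ≥ actual} + 1)/(n_trials + 1), an add-one-smoothed
  empirical permutation p-value. This assumption-free definition was
  chosen because the conventional "alpha < 0.01" usage is a tail
  probability, and the smoothed estimator is well-defined at zero
  exceedances.
* Applicability domain is reported as the count of test compounds flagged
  outside the training ranges.

## Screening cascade

Stages run strictly in order: predicted-activity cutoff, rule of five,
risk rules. The activity stage excludes compounds predicted *strictly
above* the threshold (default 20 µM; 15 µM is a noted alternative preset —
both appear in the literature on these compounds and neither is declared
canonical here, so the threshold is a plain parameter). A compound whose
prediction is missing is routed to an `unevaluated` bin rather than passed.
The rule of five uses inclusive limits (MW ≤ 500, logP ≤ 5, HBD ≤ 5,
HBA ≤ 10) with the classic one-violation allowance (configurable to zero)
and fails closed when a property is unavailable. The risk stage is a
transparent rule engine — named predicates with non-negative weights,
exclusion at total score ≥ cutoff (default 10) — standing in for
proprietary composite ADMET risk scores, whose internals are deliberately
not reproduced; the default rule set is empty. Survivors are ranked by
predicted IC₅₀ ascending (worst-case across models in multi-model mode,
ties by compound id), making reports deterministic and row-order
invariant.

One floating-point subtlety: no IEEE double maps to exactly 20.0 under
10^x for these coefficient grids, so the library-level "boundary compound"
generator returns the closest representable prediction on the passing
side; the strict boundary semantics (exactly 20 µM passes) are exercised
directly on records carrying that prediction.

## Synthetic data

The curated cell-line training tables behind the published equations were
produced with proprietary descriptor software and are not redistributable,
so the generators emulate their statistical structure instead:

* `simulate_descriptor_table` draws descriptors from configurable
  distributions (non-negative integers for count descriptors, uniform
  ranges for E-state sums) and plants activity = intercept + Σβx +
  N(0, σ). The standard recovery scenario plants the frozen U251
  coefficients among seven noise descriptors at n = 150, σ = 0.1 — sample
  size and noise chosen to match a realistic small-QSAR regime (≈110
  training compounds, residual scatter of order 0.1 log unit).
* `simulate_screening_library` draws per-compound pass labels
  Bernoulli(pass_fraction) and rejection-samples descriptor vectors until
  the frozen model's prediction lands on the required side of the
  threshold, giving exact ground truth for cascade tests (the emulated
  designed-library scale is 1,000 compounds).
* `fixture_molecules` packages 26 hand-checkable molecules (methane
  through a caged-xanthone-like polycycle) with descriptor values frozen
  from the independent oracle scripts.

What the generators do *not* emulate: real descriptor collinearity
structure, activity cliffs, measurement error correlated with chemistry,
or the actual chemical diversity of a designed library. Passing tests
therefore demonstrate that the algorithms are implemented correctly and
behave as specified under controlled conditions — not that the frozen
equations generalize to new chemistry.

## Numerical conventions

Seeds are explicit everywhere; no global random state is used or mutated.
Pure-noise calibration of the stepwise entry criterion uses a one-column
table (n = 50), for which the nominal intercept-only rate at
`f_to_enter` = 4 is ≈95%; with k candidate columns the family-wise false
entry rate grows as 1 − 0.95^k, which is expected behavior for forward
selection, not a defect. CSV output prints floats at 4 decimals (matching
the precision of the published coefficients); JSON carries full precision.
Tie-breaks are deterministic throughout (lowest column index in selection,
higher column index dropped in pruning, compound id in ranking).

## Known limitations

* The published models ship without training ranges or training data, so
  their applicability domain cannot be evaluated; predictions far from the
  caged-xanthone chemotype are extrapolations.
* `DeltaEpsilonC` and the MMFF_29/acceptor rule data are documented
  stand-ins for proprietary definitions; absolute agreement with the
  original software is not guaranteed for these descriptors.
* No 3D, conformational, stereochemical or quantum descriptors; no
  docking, metabolism or toxicity prediction — the risk engine only hosts
  user-supplied rules.
* Stepwise-forward MLR inherits the usual selection biases (inflated
  in-sample r², order dependence under strong collinearity); the
  validation battery, not the fit statistics, is the arbiter of model
  quality.
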