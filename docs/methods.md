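# Methods

## Model and workflow

The package treats an RNA secondary structure as a nested set of base
pairs; pseudoknots are out of scope, and any annotation that cannot be
written in plain dot-bracket notation is read as unpaired.  Neutrality is
always computed for a *(sequence, reference structure)* pair obtained
from a structure-annotated alignment by a fixed three-step workflow:

1. the aligned sequence and the aligned consensus structure are degapped
   simultaneously (a pair loses its partner column → both sides become
   unpaired; a pair pushed closer than the minimum hairpin distance by
   gap removal is dissolved);
2. non-canonical pairs (anything other than Watson-Crick or G-U wobble)
   are treated as single stranded;
3. the surviving structure is the reference T for the chosen metric.

Rows containing ambiguity codes (N, R, …) are skipped with a logged
reason rather than guessed: a neutrality over the 3L defined point
mutants is ill-posed for ambiguous bases.  Rows whose filtered reference
is empty are likewise skipped for the ensemble metric, which is undefined
at |T| = 0 (and, more importantly, inflates as |T| shrinks: with very few
reference pairs there is very little that a mutation can break, so
few-pair consensus structures produce deceptively high scores — the
screening caveat to keep in mind for poorly structured alignments).

## Metrics

* **SEN** (in [0,1]): mean over the 3L mutants and over N ensemble
  samples of the fraction of T's pairs retained.  Added pairs are never
  penalized.  `n_samples=0` computes the exact expectation from the
  mutant's base-pair probability matrix instead of sampling; this is
  deterministic and is the cheaper choice in large screens.
* **bp-distance** (in [0,1]): mean over mutants of 1 − d(T, MFE(S′))/L
  with d the symmetric-difference pair count.  Deterministic; penalizes
  gains and losses equally.  The normalization is by L (not by the
  maximal possible distance L/2), which compresses the usable range into
  the upper half of [0,1] but keeps the score interpretable as "pair
  changes per base".
* **PCC** (in [0,1]): mean over mutants of (1 + r)/2 where r is the
  Pearson correlation between the 0/1 paired-state vectors of T and of
  the centroid (pairs in > half) of the mutant's sampled ensemble.  The
  orientation maps identical structures to 1; a `sign_convention=
  "printed"` flag exposes the mirrored (1 − r)/2 form for comparison with
  conventions that score disruption rather than retention.  When either
  vector is constant r is undefined; the convention is 1.0 if the vectors
  are equal and 0.5 (the no-information midpoint) otherwise.

Per-mutant sampling uses one independent RNG substream per mutant
(spawned from the master seed by mutant rank), so results are bit-stable
and independent of evaluation order.

## Parameters that matter

| parameter | default | notes |
| --- | --- | --- |
| `n_samples` | 1000 | ensemble samples per mutant; 10× more does not change results, 10× fewer is visibly unstable; 0 = exact expectation (SEN only) |
| temperature | 37 °C | vienna engine; engine defaults otherwise |
| hairpin loop | ≥ 3 unpaired bases | enforced by both engines on generated/folded structures; given structures are honored except for degapping-created short pairs |
| JSD filter | < 0.01 (bits, mononucleotide) | composition match between a sequence and its robustness background |
| walk length | 4L attempted steps | neutral random walk; acceptance requires an unchanged MFE structure |
| background | 10 inverse-fold seeds × 10 walks | 100 members per sequence; a seed failing the JSD filter is regenerated up to 100 times, total failure omits the sequence |
| SVM | RBF kernel, fold-internal z-scaling, 10-fold stratified CV | defaults of scikit-learn's SVC; pooled decision values give the ROC |
| Z-score nulls | 100 dinucleotide-exact shuffles per row | sample standard deviation; sd = 0 rows contribute 0 |

## Engines

`vienna` wraps ViennaRNA (MFE, partition function, stochastic
backtracking with `uniq_ML=1`, alifold consensus, RNAinverse-style
inverse folding).  Engine name and version are written into every
provenance record because absolute numbers are engine- and
version-dependent.

`toy` is a self-contained nearest-pair model: pair energies GC/CG = −3,
AU/UA = −2, GU/UG = −1 (arbitrary units), hairpin loop ≥ 3, no other
loop terms, Boltzmann factor exp(−E/kT) with kT = 1.  It exists so that
every ensemble operation can be certified against exhaustive enumeration
(the test suite folds 50 random short sequences both ways), and it is
fast enough (numba-compiled dynamic programs) to drive the full synthetic
benchmark.  Its consensus folding is alifold-style: per-column-pair
energies are averaged over rows (rows that cannot form a canonical pair
at the columns are penalized by +1; column pairs gapped in half the rows
or with non-negative mean energy are disallowed) and the averaged matrix
is folded with the same minimum-energy recursion.  A per-row
majority-vote consensus was tried first and rejected: shuffled decoy
alignments share almost no per-row MFE pairs, so their consensus came out
empty or single-pair, which both knocks every decoy row out of the
pipeline and triggers the few-pair score inflation described above.

Numerical choices: MFE ties are broken toward the lexicographically
smallest dot-bracket string (deterministic across platforms); partition
functions are unscaled doubles, which overflows only beyond L ≈ 450 under
the toy energies — far past the intended use; exact pair probabilities
come from an outside recursion over canonical cells; stochastic
backtracking consumes pre-drawn uniforms (at most L per structure), so a
sample is a pure function of (engine, sequence, N, seed).

Inverse folding is an adaptive walk minimizing the base-pair distance to
the target (50 restarts × 10L steps); the target is deliberately not
forced — consensus structures are often not anyone's MFE — and success
means finishing within half the target's pair count.  Restarts can be
biased toward a caller-supplied base composition (bases drawn without
replacement from the target counts, greedy canonical pair assignment):
the robustness module uses this so that composition-filtered backgrounds
reach their full 100 members within the fixed regeneration budget.

## Synthetic data: what it does and does not emulate

The fixture generator emulates the statistical structure the method
assumes of a curated seed alignment: a shared consensus structure, stems
that are canonical in every row, compensatory (covarying) substitutions
at paired sites, and tunable divergence (default substitution rate 0.15
per site, 5 rows).  Ancestor stems draw pair types as GC/CG 0.30 each,
AU/UA 0.15, GU/UG 0.05 — the GC-enriched composition typical of conserved
stems, and the property that makes the designed structure
thermodynamically dominant for every row.  With covariation off, paired
sites are simply held fixed, so rows remain structure-compatible either
way.

Decoys are per-row dinucleotide-exact shuffles (Euler-path method) with
each row's gap columns left in place and the consensus re-predicted by
the engine; a column-permutation decoy is available behind
`mode="columns"`.  The generator does **not** emulate genomic flanking
sequence, alignment errors, indel structure (fixtures are gap-free),
length heterogeneity, or tertiary-contact constraints.  Passing the
synthetic benchmark therefore shows that the pipeline detects the
conserved-structure signal it was built to detect, not that the
classifier transfers to any particular genomic screen.

The designed "neutral plateau" used by the robustness tests is an all-GC
stem over an A/U loop: the strong GC pairs dominate every 1-mutant
ensemble while the mixed composition keeps the composition-matched
background class diverse (alternative inverse folds must park G/C in
loops or build weak A-U stems), so the designed arrangement sits at the
top of its class.  An earlier all-GC/all-A design was discarded: its
composition class collapses to near-copies of itself, making the
strictly-greater robustness comparison unwinnable by construction.

## Robustness screen

A sequence is robust iff its neutrality strictly exceeds the background
mean. Background members are scored with the same metric against the same
reference structure as the wild type.  Walk acceptance compares the
candidate's MFE structure to the walk-start's own MFE by default (the
natural reference for inverse-folded seeds); a `walk_reference="target"`
flag switches the comparison to the alignment structure.  Walk end points
that drift outside the JSD filter are re-walked (fresh substream, up to
20 times) and fall back to the seed sequence itself — a legal walk
outcome — so the filter holds for every member.

## Problem sizes in the shipped tests and acceptance script

The synthetic benchmark runs 30 structured alignments (L = 60, 5 rows)
against 30 decoys at N = 1000; the robustness comparison runs 20
replicates of designed-plateau vs random-seed wild types with reduced
5 × 4-member backgrounds (the full 10 × 10 background is exercised once);
oracle checks enumerate 50 sequences of L ≤ 12.  These sizes were chosen
so the whole suite completes in minutes on one CPU while every module is
driven through its production code path.

## Known limitations

* Nested structures only; WUSS pseudoknot annotation is dropped to
  unpaired.
* The toy model has no stacking, dangles or loop-size terms; its
  ensembles are more diffuse than thermodynamic reality, so absolute
  neutrality values are not comparable between engines — only within one
  engine.
* Few-pair reference structures inflate the ensemble metric (see above);
  interpret scores for alignments with a handful of consensus pairs with
  care.
* The structure-disruption regression (eSDC, top-50% labeling) follows
  the standard recipe but position-level disruption prediction is
  intrinsically hard; treat its AUC as a diagnostic, not a product.

## Scoring real alignment collections

For Rfam-style data use the `vienna` engine with Stockholm input
(`given` structure source for seed alignments, `predicted` to re-fold).
Expected qualitative behavior, based on the synthetic benchmark and the
design of the metrics: structured seed alignments should score well above
their dinucleotide-shuffled decoys under the ensemble metric, and a
majority of bona fide regulatory structures should be called robust.
Absolute values depend on the ViennaRNA version and alignment curation;
budget roughly a minute per hundred-base sequence at N = 1000 (the exact
mode and the parallel-friendly per-sequence structure of the computation
both help at scale).
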