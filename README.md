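# senrna — structural ensemble neutrality for RNA alignments

`senrna` measures how well RNA sequences tolerate point mutations without
losing a biologically meaningful secondary structure, and uses that signal
to tell alignments of genuinely structured RNAs apart from decoy
alignments.  It is aimed at people doing *de novo* non-coding-RNA
discovery or studying the mutational robustness of regulatory RNA
structures (riboswitches, bacterial cis-regulators, …).

## The statistic

For a gap-free sequence *S* of length *L* with a reference structure *T*
taken from a structure-annotated alignment (e.g. an Rfam-style `SS_cons`
line, degapped together with the sequence and stripped of non-canonical
pairs), consider the 3*L* single-point mutants *S′* ∈ 1mut(*S*).  For each
mutant, *N* structures *T′* are sampled with replacement from its
Boltzmann ensemble.  The **structural ensemble neutrality** is

    SEN = (1 / 3L) Σ_{S′}  (1 / N) Σ_{T′}  |T ∩ T′| / |T|

— the mean fraction of reference base pairs retained across the mutant
ensembles.  Extra pairs formed by a mutant are *not* penalized; only loss
of the core structure counts.  A positional profile SEN(*i*) averages the
same quantity over the three mutants at each position.

Two classical neutrality measures are implemented for comparison on the
same degap-and-filter workflow: the normalized base-pair distance
(1 − d(T, MFE(S′))/L averaged over mutants, where d is the symmetric
difference of pair sets) and a Pearson-correlation score ((1 + r)/2, with
r correlating the paired/unpaired indicator vectors of T and the centroid
of the mutant's sampled ensemble).

On top of the metrics the package provides:

* **robustness verdicts** — *S* is mutationally robust iff its neutrality
  strictly exceeds the mean neutrality of ~100 background sequences built
  from 10 inverse-fold seeds × 10 neutral random walks (4L attempted
  steps, compensatory mutations at paired sites), composition-matched to
  *S* by Jensen-Shannon divergence < 0.01;
* **classification** — the standard six alignment features (Z-score of
  the MFE, structure conservation index, mean stem entropy, mean stem
  mutual information, mean pairwise identity, number of sequences) plus
  neutrality, evaluated with an RBF SVM under 10-fold stratified CV
  (ROC/AUC), and an eSDC = (1 − PCC)·√L structure-disruption analysis;
* **synthetic data** — structured fixture alignments with covarying
  canonical stems, dinucleotide-exact shuffled decoys (Euler-path
  method), subalignment sampling and ΔSEN alignment-quality diagnostics.

Two folding engines are available behind one interface: `vienna`
(ViennaRNA: MFE, partition function, stochastic backtracking, alifold
consensus, RNAinverse) for production use, and `toy`, a self-contained
nearest-pair energy model (GC −3, AU −2, GU −1, hairpin ≥ 3, kT = 1) that
is exactly enumerable and therefore testable against brute force.

## Worked example

Library use — the toy engine's canonical hairpin:

```python
from senrna import Sequence, parse_dot_bracket, sen_neutrality, get_engine

engine = get_engine("toy")
s = Sequence("GGGAAACCC")
t = parse_dot_bracket("(((...)))")
r = sen_neutrality(s, t, engine, n_samples=1000, seed=42)
print(r.value)                     # 0.512962962962963
print([round(float(v), 3) for v in r.per_position])
# [0.301, 0.39, 0.31, 0.777, 0.791, 0.77, 0.401, 0.464, 0.412]
```

About half the reference pairs survive a random point mutation on
average; the profile shows loop positions (0.77–0.79) are far more
neutral than stem positions (0.30–0.46) — mutations in stems disrupt
structure, mutations in loops rarely do.

Command line — generate a structured fixture alignment and score it with
all three metrics:

```sh
senrna fixtures --n-alignments 1 --length 40 --seed 7 --out fx
senrna neutrality --input fx/structured001.sto --metric all \
       --n-samples 1000 --seed 7 --out out
head -6 out/neutrality.tsv
```

```text
sequence_id	metric	value	n_samples	seed	skip_reason
seq1	SEN	0.09521428571	1000	1201125462
seq2	SEN	0.1748452381	1000	1471499524
seq3	SEN	0.2163214286	1000	1684166798
seq4	SEN	0.4426369048	1000	1694716536
seq5	SEN	0.3819630952	1000	1956387801
```

`senrna robustness` writes per-sequence robustness verdicts and the
fraction of robust sequences; `senrna benchmark` runs the full
structured-vs-decoy classification benchmark (features, SVM AUCs,
Wilcoxon separation, cross-metric Spearman).  Every command writes a JSON
provenance sidecar, and a rerun with the same configuration, seed and
engine reproduces each output byte for byte.

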