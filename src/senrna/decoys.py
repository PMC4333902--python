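"""Synthetic structured alignments and negative decoys.

The fixture generator emulates the statistical signature of a curated
structured-RNA seed alignment: a conserved consensus structure, canonical
(and, with covariation on, compensatorily co-varying) base pairs, and
controlled sequence divergence.  Decoys are per-row dinucleotide-exact
shuffles (Euler-path method) whose consensus structure is re-predicted by
a folding engine, mirroring how negative alignments are built for
structured-RNA classification benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engines.base import FoldingEngine, bp_distance
from .neutrality import NeutralityResult
from .robustness import COMPENSATORY
from .structures import (
    SecondaryStructure,
    Sequence,
    StructuredAlignment,
    parse_dot_bracket,
)

CANONICAL_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]

#: ancestor stem pair-type frequencies: GC-rich with occasional wobble,
#: the composition typical of conserved structured-RNA stems
ANCESTOR_PAIR_WEIGHTS = np.array([0.30, 0.30, 0.15, 0.15, 0.05, 0.05])


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson Euler-path method)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of ``seq`` preserving its exact dinucleotide
    counts (and hence mononucleotide counts).

    Classic Euler-path construction: view characters as vertices and
    adjacent pairs as directed edges; draw a random "last edge" per vertex
    until those edges form a tree into the final vertex, then shuffle the
    remaining edges and walk the Euler path.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last_vertex = seq[-1]
    sources = [v for v in vertices if v != last_vertex and edges[v]]
    while True:
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in sources}
        # tree check: from every source, following last edges reaches last_vertex
        ok = True
        for v in sources:
            cur, hops = v, 0
            while cur != last_vertex:
                if cur not in last_edge or hops > len(vertices):
                    ok = False
                    break
                cur = last_edge[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool
    out = [seq[0]]
    counters = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle_alignment(
    alignment: StructuredAlignment,
    engine: FoldingEngine,
    seed: int = 0,
    mode: str = "dinucleotide",
) -> StructuredAlignment:
    """Decoy alignment: each row's degapped sequence is shuffled
    (dinucleotide-exact), gaps are reinserted at their original columns,
    and the consensus structure is re-predicted with the engine.

    ``mode="columns"`` instead permutes alignment columns jointly across
    rows (the coarser decoy sometimes used for the same purpose).
    """
    rng = np.random.default_rng(seed)
    if mode == "columns":
        perm = rng.permutation(alignment.width)
        rows = [
            (name, "".join(row[c] for c in perm)) for name, row in alignment.rows
        ]
    elif mode == "dinucleotide":
        rows = []
        for name, row in alignment.rows:
            cols = [c for c, ch in enumerate(row) if ch not in "-."]
            degapped = "".join(row[c] for c in cols)
            shuffled = dinucleotide_shuffle_sequence(degapped, rng)
            chars = list(row)
            for c, ch in zip(cols, shuffled):
                chars[c] = ch
            rows.append((name, "".join(chars)))
    else:
        raise ValueError("mode must be 'dinucleotide' or 'columns'")
    decoy = StructuredAlignment(
        rows,
        None,
        "predicted",
        comments=[f"decoy: {mode} shuffle, seed={seed}, engine={engine.name}"],
    )
    decoy.consensus = engine.consensus_structure(decoy)
    return decoy


# ---------------------------------------------------------------------------
# structured fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic structured alignment."""

    target_structure: SecondaryStructure
    n_sequences: int = 5
    substitution_rate: float = 0.15
    covariation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0,1]")
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")


def random_structure(
    length: int,
    rng: np.random.Generator,
    stem_range: tuple[int, int] = (4, 8),
    loop_range: tuple[int, int] = (3, 7),
    spacer_range: tuple[int, int] = (0, 3),
) -> SecondaryStructure:
    """A random multi-hairpin nested structure: stems of 4-8 pairs closed
    over loops of 3-7 bases, separated by short unpaired spacers."""
    chars = ["."] * length
    pos = 0
    pairs = set()
    while True:
        spacer = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        stem = int(rng.integers(stem_range[0], stem_range[1] + 1))
        loop = int(rng.integers(loop_range[0], loop_range[1] + 1))
        start = pos + spacer
        end = start + 2 * stem + loop
        if end > length:
            break
        for s in range(stem):
            i, j = start + s, end - 1 - s
            pairs.add((i, j))
            chars[i], chars[j] = "(", ")"
        pos = end
    return SecondaryStructure(frozenset(pairs), length)


def synthetic_structured_alignment(spec: FixtureSpec) -> StructuredAlignment:
    """Generate a gap-free alignment whose rows diverge from a common
    structure-compatible ancestor.

    Paired sites of the ancestor hold random canonical pairs.  Each row
    mutates unpaired sites independently at ``substitution_rate``; with
    ``covariation=True`` each *pair* is additionally redrawn at the same
    rate through the compensatory rule, so paired columns co-vary while
    staying canonical.  With ``covariation=False`` paired sites are held
    fixed (rows stay structure-compatible either way).
    """
    t = spec.target_structure
    rng = np.random.default_rng(spec.seed)
    length = t.length
    partner = t.partner_array()
    ancestor = [""] * length
    for i in range(length):
        if partner[i] == -1:
            ancestor[i] = "ACGU"[int(rng.integers(4))]
        elif partner[i] > i:
            a, b = CANONICAL_CHOICES[int(rng.choice(6, p=ANCESTOR_PAIR_WEIGHTS))]
            ancestor[i], ancestor[partner[i]] = a, b
    rows = []
    for r in range(spec.n_sequences):
        chars = list(ancestor)
        for i in range(length):
            if partner[i] == -1:
                if rng.random() < spec.substitution_rate:
                    chars[i] = "ACGU".replace(chars[i], "")[int(rng.integers(3))]
            elif partner[i] > i and spec.covariation:
                if rng.random() < spec.substitution_rate:
                    new = "ACGU".replace(chars[i], "")[int(rng.integers(3))]
                    chars[i] = new
                    options = COMPENSATORY[new]
                    chars[partner[i]] = options[int(rng.integers(len(options)))]
        rows.append((f"seq{r + 1}", "".join(chars)))
    return StructuredAlignment(
        rows,
        t.dot_bracket(),
        "given",
        comments=[
            f"synthetic structured fixture: rate={spec.substitution_rate}, "
            f"covariation={spec.covariation}, seed={spec.seed}"
        ],
    )


def neutral_plateau_fixture(
    stem_len: int = 4, loop_len: int = 8
) -> tuple[Sequence, SecondaryStructure]:
    """A designed neutral plateau: an all-GC stem over an A/U loop.

    The strong GC pairs dominate each 1-mutant ensemble, so the reference
    pairs are well retained; the mixed A/C/G/U composition leaves the
    composition-matched background class diverse (alternative inverse
    folds must park G/C in loops or use weak A-U stems), which puts the
    designed arrangement near the top of its class — the property the
    robustness screen detects.  The sequence's MFE structure contains the
    designed stem (the loop edge may zip an extra pair or two).
    """
    half = stem_len // 2 + stem_len % 2
    left = "G" * half + "C" * (stem_len - half)
    comp = {"G": "C", "C": "G"}
    right = "".join(comp[c] for c in reversed(left))
    loop = ("AAUU" * (loop_len // 4 + 1))[:loop_len]
    seq = Sequence(left + loop + right)
    struct = parse_dot_bracket("(" * stem_len + "." * loop_len + ")" * stem_len)
    return seq, struct


# ---------------------------------------------------------------------------
# subalignments & alignment-quality analysis
# ---------------------------------------------------------------------------

def subalignment_sample(
    alignment: StructuredAlignment,
    seed: int = 0,
    engine: FoldingEngine | None = None,
) -> StructuredAlignment:
    """Random subalignment of 3-6 rows (capped at the row count), with
    all-gap columns removed; the consensus is re-predicted when the
    alignment's structure is of predicted origin and an engine is given."""
    if alignment.n_rows < 3:
        raise ValueError("subalignment sampling needs at least 3 rows")
    rng = np.random.default_rng(seed)
    k = min(int(rng.integers(3, 7)), alignment.n_rows)
    chosen = sorted(rng.choice(alignment.n_rows, size=k, replace=False).tolist())
    rows = [alignment.rows[i] for i in chosen]
    keep = [
        c
        for c in range(alignment.width)
        if any(row[c] not in "-." for _n, row in rows)
    ]
    rows = [(name, "".join(row[c] for c in keep)) for name, row in rows]
    consensus = None
    if alignment.consensus is not None:
        old = parse_dot_bracket(alignment.consensus)
        col_map = {c: n for n, c in enumerate(keep)}
        pairs = frozenset(
            (col_map[i], col_map[j])
            for i, j in old.pairs
            if i in col_map and j in col_map
        )
        consensus = SecondaryStructure(pairs, len(keep)).dot_bracket()
    sub = StructuredAlignment(rows, consensus, alignment.structure_source)
    if alignment.structure_source == "predicted" and engine is not None:
        sub.consensus = engine.consensus_structure(sub)
    return sub


@dataclass(frozen=True)
class DeltaSen:
    """SEN(full alignment) - SEN(subalignment) for one sequence, with
    structure-difference diagnostics between the two reference structures
    (computed on the degapped, canonical-filtered structures)."""

    sequence_id: str
    delta: float
    reference_bp_distance: int | None = None
    bp_count_ratio: float | None = None


def delta_sen(
    full_result: NeutralityResult,
    sub_result: NeutralityResult,
    full_structure: SecondaryStructure | None = None,
    sub_structure: SecondaryStructure | None = None,
) -> DeltaSen:
    """Alignment-quality effect on SEN for one underlying sequence."""
    if full_result.sequence_id != sub_result.sequence_id:
        raise ValueError(
            f"mismatched sequence ids: {full_result.sequence_id!r} vs "
            f"{sub_result.sequence_id!r}"
        )
    dist = ratio = None
    if full_structure is not None and sub_structure is not None:
        dist = bp_distance(full_structure, sub_structure)
        ratio = len(full_structure) / len(sub_structure) if len(sub_structure) else np.inf
    return DeltaSen(
        full_result.sequence_id, full_result.value - sub_result.value, dist, ratio
    )
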