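"""Core RNA domain types: sequences, nested secondary structures and
structure-annotated alignments.

Internally all coordinates are 0-based; human-facing reports (TSV output,
error messages about alignment columns) use 1-based positions.

A :class:`SecondaryStructure` is a set of nested base pairs ``(i, j)`` with
``i < j``.  Pseudoknots are out of scope: WUSS annotation characters that
cannot be expressed in plain dot-bracket notation (pseudoknot letters,
``A``/``a`` …) are read as unpaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical Watson-Crick + wobble pairs
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN_LOOP = 3

ALPHABET = "ACGU"

#: WUSS/dot-bracket opening brackets and their closers
_BRACKETS = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}
_GAP_CHARS = set(".-_~,:")


class StructureParseError(ValueError):
    """Raised on malformed dot-bracket / WUSS strings."""


@dataclass(frozen=True)
class Sequence:
    """A gap-free RNA sequence over {A, C, G, U}.

    Input is normalized: ``T``→``U`` and lowercase→uppercase.  Sequences
    containing other characters (ambiguity codes such as N, R, Y …) raise
    :class:`AmbiguousSequenceError`; callers that iterate over alignments
    catch this and record the row as skipped.
    """

    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        bad = set(norm) - set(ALPHABET)
        if bad:
            raise AmbiguousSequenceError(
                f"sequence contains non-ACGU characters: {sorted(bad)}"
            )
        if len(norm) < 1:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, i):
        return self.residues[i]

    def composition(self) -> np.ndarray:
        """Mononucleotide frequency vector in A, C, G, U order."""
        counts = np.array([self.residues.count(b) for b in ALPHABET], dtype=float)
        return counts / counts.sum()


class AmbiguousSequenceError(ValueError):
    """Sequence contains bases outside {A, C, G, U} after normalization."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs on a sequence of length ``length``."""

    pairs: frozenset
    length: int

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        seen = set()
        for i, j in pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of bounds for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        # nesting check: no two pairs may cross
        events = sorted([(i, 1, j) for i, j in pairs] + [(j, -1, i) for i, j in pairs])
        stack2: list[tuple[int, int]] = []
        for pos, kind, other in events:
            if kind == 1:
                stack2.append((pos, other))
            else:
                if not stack2 or stack2[-1] != (other, pos):
                    raise ValueError("crossing (pseudoknotted) pairs are not representable")
                stack2.pop()
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        """Number of base pairs |T|."""
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """Length-L int array: partner index, or -1 if unpaired."""
        p = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def __str__(self) -> str:
        return self.dot_bracket()


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Parse a dot-bracket / WUSS string into a :class:`SecondaryStructure`.

    All four bracket classes are accepted (WUSS uses ``<>`` for simple
    stems); any other character — WUSS gap/unpaired annotation, pseudoknot
    letters — is treated as unpaired.  Unbalanced brackets raise
    :class:`StructureParseError` naming the offending index.
    """
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs = set()
    for idx, ch in enumerate(db):
        if ch in _BRACKETS:
            stacks[ch].append(idx)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise StructureParseError(
                    f"unbalanced structure: unmatched '{ch}' at index {idx}"
                )
            pairs.add((stack.pop(), idx))
        # everything else (., -, _, ~, letters, commas) is unpaired
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unbalanced structure: unmatched '{opener}' at index {stack[-1]}"
            )
    return SecondaryStructure(frozenset(pairs), len(db))


def structure_projections(t: SecondaryStructure) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency-matrix and binary-vector projections of a structure.

    Returns ``(M, V)`` where ``M`` is the L×L symmetric 0/1 adjacency
    matrix (``M[i, j] = 1`` iff i pairs j) and ``V`` the length-L 0/1
    vector marking paired positions.  ``V.sum() == 2 * len(t)``.
    """
    m = np.zeros((t.length, t.length), dtype=np.int8)
    v = np.zeros(t.length, dtype=np.int8)
    for i, j in t.pairs:
        m[i, j] = m[j, i] = 1
        v[i] = v[j] = 1
    return m, v


def degap_pair(
    aligned_seq: str, aligned_structure: str
) -> tuple[Sequence, SecondaryStructure]:
    """Simultaneously degap an aligned sequence and its aligned structure.

    Columns where the sequence carries a gap are removed from both; a pair
    whose partner column is deleted becomes unpaired.  Pairs that end up
    closer than the minimum hairpin-loop distance after degapping are
    dissolved to unpaired (degapping can create physically impossible
    short-range pairs; given structures are otherwise accepted as-is).
    """
    if len(aligned_seq) != len(aligned_structure):
        raise ValueError(
            f"aligned lengths differ: sequence {len(aligned_seq)} vs "
            f"structure {len(aligned_structure)}"
        )
    struct = parse_dot_bracket(aligned_structure)
    keep = [idx for idx, ch in enumerate(aligned_seq) if ch not in "-." ]
    col_to_new = {c: n for n, c in enumerate(keep)}
    seq = Sequence("".join(aligned_seq[c] for c in keep))
    pairs = set()
    for i, j in struct.pairs:
        if i in col_to_new and j in col_to_new:
            ni, nj = col_to_new[i], col_to_new[j]
            if nj - ni > MIN_HAIRPIN_LOOP:
                pairs.add((ni, nj))
    return seq, SecondaryStructure(frozenset(pairs), len(seq))


def canonical_filter(s: Sequence, t: SecondaryStructure) -> SecondaryStructure:
    """Drop non-canonical pairs: everything but Watson-Crick and G-U wobble
    is considered single stranded.  Idempotent."""
    if len(s) != t.length:
        raise ValueError("sequence/structure length mismatch")
    pairs = frozenset(
        (i, j) for i, j in t.pairs if (s[i], s[j]) in CANONICAL_PAIRS
    )
    return SecondaryStructure(pairs, t.length)


@dataclass
class StructuredAlignment:
    """An RNA multiple sequence alignment with an aligned consensus structure.

    ``structure_source`` records whether the consensus came with the
    alignment ("given", e.g. an Rfam SS_cons line) or was predicted by a
    folding engine ("predicted").  ``consensus`` may be ``None`` only for
    structure_source="predicted" before prediction has run.
    """

    rows: list  # list of (identifier, aligned sequence) tuples
    consensus: str | None
    structure_source: str = "given"
    comments: list = field(default_factory=list)  # "#=GF"-style provenance lines

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for name, row in self.rows:
            if len(row) != width:
                raise ValueError(f"ragged alignment: row '{name}' has length {len(row)}")
        if self.consensus is not None:
            if len(self.consensus) != width:
                raise ValueError("consensus length differs from alignment width")
            parse_dot_bracket(self.consensus)  # validates balance
        if self.structure_source not in ("given", "predicted"):
            raise ValueError("structure_source must be 'given' or 'predicted'")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def consensus_structure(self) -> SecondaryStructure:
        if self.consensus is None:
            raise ValueError("alignment has no consensus structure yet")
        return parse_dot_bracket(self.consensus)

    def degapped_row(self, index: int) -> tuple[str, Sequence, SecondaryStructure]:
        """(identifier, degapped sequence, degapped per-row structure)."""
        if self.consensus is None:
            raise ValueError("alignment has no consensus structure yet")
        name, row = self.rows[index]
        seq, struct = degap_pair(row, self.consensus)
        return name, seq, struct


def _normalize_aligned(seq: str) -> str:
    """Uppercase, T→U; gaps unified to '-'."""
    out = []
    for ch in seq.upper().replace("T", "U"):
        out.append("-" if ch in "-._~" else ch)
    return "".join(out)


def read_stockholm(path, structure_source: str = "given") -> StructuredAlignment:
    """Read a Stockholm alignment (with ``#=GC SS_cons``) into a
    :class:`StructuredAlignment`.

    WUSS annotation in SS_cons is accepted; it is kept verbatim in
    ``consensus`` (parsing maps non-nested symbols to unpaired).  A missing
    SS_cons line is an error when ``structure_source="given"``; with
    ``"predicted"`` the consensus is left unset for a fold backend to fill.
    """
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "stockholm")
    rows = [(rec.id, _normalize_aligned(str(rec.seq))) for rec in aln]
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None and structure_source == "given":
        raise ValueError(f"{path}: no #=GC SS_cons line but structure_source='given'")
    return StructuredAlignment(rows, ss, structure_source)


def write_stockholm(alignment: StructuredAlignment, path) -> None:
    """Write a minimal Stockholm file that round-trips with
    :func:`read_stockholm` (rows, identifiers, consensus, #=GF comments)."""
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for comment in alignment.comments:
            fh.write(f"#=GF CC {comment}\n")
        name_w = max(len(name) for name, _ in alignment.rows)
        name_w = max(name_w, len("#=GC SS_cons"))
        for name, row in alignment.rows:
            fh.write(f"{name:<{name_w}} {row}\n")
        if alignment.consensus is not None:
            fh.write(f"{'#=GC SS_cons':<{name_w}} {alignment.consensus}\n")
        fh.write("//\n")
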