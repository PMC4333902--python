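"""Independent brute-force oracle for the toy energy model.

Everything here is computed by exhaustive enumeration of all loop-legal
nested structures — deliberately written without reference to the
engine's dynamic programs, so it can certify them on small sequences.
"""

from __future__ import annotations

import math
from functools import lru_cache

ORACLE_MIN_LOOP = 3
ORACLE_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_structures(seq: str) -> list[frozenset]:
    """All nested structures (sets of canonical pairs, hairpin loop >= 3)
    of ``seq``, including the empty structure."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple:
        if i >= j:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + ORACLE_MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in ORACLE_PAIR_ENERGY:
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return tuple(out)

    return list(rec(0, len(seq) - 1))


def structure_energy(seq: str, pairs) -> float:
    return sum(ORACLE_PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs)


def to_dot_bracket(pairs, length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def mfe_by_enumeration(seq: str) -> tuple[str, float]:
    """(lexicographically smallest co-minimal dot-bracket, MFE energy)."""
    best_e = math.inf
    best_db = None
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        db = to_dot_bracket(pairs, len(seq))
        if e < best_e - 1e-12 or (abs(e - best_e) < 1e-12 and db < best_db):
            best_e, best_db = e, db
    return best_db, best_e


def boltzmann_distribution(seq: str) -> dict[frozenset, float]:
    """Exact structure probabilities, kT = 1."""
    structures = enumerate_structures(seq)
    weights = [math.exp(-structure_energy(seq, p)) for p in structures]
    z = sum(weights)
    return {p: w / z for p, w in zip(structures, weights)}


def bpp_by_enumeration(seq: str) -> dict[tuple, float]:
    """Exact pair probabilities P(i,j) (i < j), zero entries omitted."""
    probs: dict[tuple, float] = {}
    for pairs, p in boltzmann_distribution(seq).items():
        for pair in pairs:
            probs[pair] = probs.get(pair, 0.0) + p
    return probs


def exact_sen_term(seq: str, reference_pairs: frozenset) -> float:
    """Exact expectation over the Boltzmann ensemble of the fraction of
    reference pairs retained (the per-mutant SEN term)."""
    assert reference_pairs
    total = 0.0
    for pairs, p in boltzmann_distribution(seq).items():
        total += p * len(reference_pairs & pairs) / len(reference_pairs)
    return total


def exact_sen_neutrality(seq: str, reference_pairs: frozenset) -> float:
    """Exact SEN: mean exact per-mutant term over all 3L mutants."""
    terms = []
    for i in range(len(seq)):
        for b in "ACGU":
            if b != seq[i]:
                terms.append(exact_sen_term(seq[:i] + b + seq[i + 1:], reference_pairs))
    return sum(terms) / len(terms)


def mfe_bp_neutrality(seq: str, reference_pairs: frozenset) -> float:
    """Oracle for normalized base-pair-distance neutrality: enumerate every
    mutant's MFE structure directly."""
    length = len(seq)
    terms = []
    for i in range(length):
        for b in "ACGU":
            if b != seq[i]:
                mutant = seq[:i] + b + seq[i + 1:]
                db, _ = mfe_by_enumeration(mutant)
                mfe_pairs = dot_bracket_pairs(db)
                d = len(reference_pairs.symmetric_difference(mfe_pairs))
                terms.append(1.0 - d / length)
    return sum(terms) / len(terms)


def dot_bracket_pairs(db: str) -> frozenset:
    stack = []
    pairs = set()
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            pairs.add((stack.pop(), idx))
    return frozenset(pairs)


def random_rna(rng, length: int) -> str:
    return "".join("ACGU"[rng.integers(4)] for _ in range(length))
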