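"""Sequence neutrality: 1-mutant neighborhoods, sampled-ensemble summaries
and the three neutrality metrics.

For a gap-free sequence S of length L folding into a reference structure
T (taken from an alignment, not from S's own MFE), neutrality is the mean
structural similarity between T and the structures adopted by the 3L
1-mutant neighbors of S.  Three distance functions are supported:

``SEN``
    structural ensemble neutrality — for each mutant, the mean fraction of
    T's base pairs retained across N structures sampled from the mutant's
    Boltzmann ensemble.  Added pairs are not penalized.  With
    ``n_samples=0`` the expectation is computed exactly from the mutant's
    base-pair probability matrix instead of sampling.
``bp_distance``
    1 - d(T, MFE(mutant)) / L averaged over mutants, where d is the
    base-pair set symmetric difference.  Penalizes additions and losses
    equally.
``PCC``
    (1 + r)/2 averaged over mutants, where r is the Pearson correlation
    between the paired/unpaired indicator vectors of T and of the
    centroid of the mutant's sampled ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engines.base import EnsembleSample, FoldingEngine, bp_distance
from .structures import (
    ALPHABET,
    AmbiguousSequenceError,
    SecondaryStructure,
    Sequence,
    StructuredAlignment,
    canonical_filter,
    structure_projections,
)

logger = logging.getLogger(__name__)

METRICS = ("SEN", "bp_distance", "PCC")

DEFAULT_N_SAMPLES = 1000  # 10x more does not change results; 10x fewer is unstable


@dataclass(frozen=True)
class MutantSet:
    """All 3L single-point mutants of a parent sequence, position-major,
    base order A < C < G < U within each position."""

    parent: Sequence
    mutants: tuple

    @classmethod
    def of(cls, parent: Sequence) -> "MutantSet":
        muts = []
        for i in range(len(parent)):
            for b in ALPHABET:
                if b != parent[i]:
                    muts.append(
                        Sequence(parent.residues[:i] + b + parent.residues[i + 1:])
                    )
        return cls(parent, tuple(muts))

    def __len__(self) -> int:
        return len(self.mutants)

    def by_position(self, i: int) -> tuple:
        """The 3 mutants at position i."""
        return self.mutants[3 * i: 3 * i + 3]


def mutant_neighbors(s: Sequence) -> MutantSet:
    """Enumerate the 3L 1-mutant neighbors of ``s``."""
    return MutantSet.of(s)


@dataclass(frozen=True)
class BasePairProbMatrix:
    """Symmetric L×L matrix of pair probabilities; ``n_samples == 0``
    marks an exactly computed matrix."""

    entries: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        e = self.entries
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("entries must be a square matrix")


def sampled_bprob(sample: EnsembleSample) -> BasePairProbMatrix:
    """Mean adjacency matrix over an ensemble sample (pair frequency)."""
    n, length = sample.partners.shape
    p = np.zeros((length, length))
    rows = np.repeat(np.arange(length)[None, :], n, axis=0)
    mask = sample.partners > rows  # count each pair once
    i_idx = rows[mask]
    j_idx = sample.partners[mask]
    np.add.at(p, (i_idx, j_idx), 1.0)
    p /= n
    p = p + p.T
    return BasePairProbMatrix(p, n)


def centroid_structure(sample: EnsembleSample) -> SecondaryStructure:
    """Pairs occurring in strictly more than half of the sampled
    structures.  Such pairs cannot conflict, so the result is always a
    valid structure."""
    p = sampled_bprob(sample).entries
    length = p.shape[0]
    ii, jj = np.where(np.triu(p, 1) > 0.5)
    return SecondaryStructure(frozenset(zip(ii.tolist(), jj.tolist())), length)


def sen_distance(t: SecondaryStructure, sample: EnsembleSample) -> float:
    """Mean fraction of T's base pairs retained across the sample.

    Extra pairs in the sampled structures are not penalized; undefined for
    an empty reference structure.
    """
    if len(t) == 0:
        raise ValueError("sen_distance undefined for an empty reference structure")
    retained = 0
    for i, j in t.pairs:
        retained += int(np.count_nonzero(sample.partners[:, i] == j))
    return retained / (sample.n * len(t))


@dataclass
class NeutralityResult:
    """Per-sequence neutrality: global value in [0,1], optional length-L
    positional profile (the profile averages to the global value)."""

    sequence_id: str
    metric: str
    value: float
    per_position: np.ndarray | None
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"neutrality value {self.value} outside [0,1]")


def _mutant_seed(seed: int, rank: int) -> np.random.SeedSequence:
    """Independent substream per mutant, indexed by mutant rank, so results
    do not depend on evaluation order."""
    return np.random.SeedSequence(seed, spawn_key=(rank,))


def _sen_terms(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Per-mutant SEN terms d(T, sample of mutant), position-major order."""
    if len(t) == 0:
        raise ValueError("SEN undefined for an empty reference structure")
    mutants = mutant_neighbors(s)
    pairs = sorted(t.pairs)
    terms = np.empty(len(mutants))
    for rank, mutant in enumerate(mutants.mutants):
        if n_samples == 0:
            p = engine.exact_base_pair_probabilities(mutant)
            terms[rank] = float(np.mean([p[i, j] for i, j in pairs]))
        else:
            sample = engine.sample_structures(mutant, n_samples, _mutant_seed(seed, rank))
            terms[rank] = sen_distance(t, sample)
    return terms


def sen_neutrality(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    sequence_id: str = "",
) -> NeutralityResult:
    """Structural ensemble neutrality: mean SEN term over all 3L mutants.

    ``n_samples=0`` switches to the exact expectation (mean of T's pair
    probabilities under each mutant's ensemble) — deterministic and
    seed-independent.
    """
    terms = _sen_terms(s, t, engine, n_samples, seed)
    profile = terms.reshape(-1, 3).mean(axis=1)
    return NeutralityResult(
        sequence_id, "SEN", float(terms.mean()), profile, n_samples, seed
    )


def positional_neutrality(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """SEN(i): mean SEN term over the 3 mutants at each position.  The
    profile mean equals the global SEN under the same seed policy."""
    return sen_neutrality(s, t, engine, n_samples, seed).per_position


def bp_distance_neutrality(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    sequence_id: str = "",
) -> NeutralityResult:
    """Normalized base-pair-distance neutrality: mean over mutants of
    1 - d(T, MFE(mutant)) / L.  Deterministic (MFE only, no sampling)."""
    mutants = mutant_neighbors(s)
    length = len(s)
    terms = np.empty(len(mutants))
    for rank, mutant in enumerate(mutants.mutants):
        d = bp_distance(t, engine.mfe_structure(mutant))
        terms[rank] = 1.0 - d / length
    profile = terms.reshape(-1, 3).mean(axis=1)
    return NeutralityResult(sequence_id, "bp_distance", float(terms.mean()), profile, 0, 0)


def _pcc_term(
    v_ref: np.ndarray, v_cent: np.ndarray, sign_convention: str
) -> float:
    """(1 ± r)/2 for one mutant; degenerate (constant) vectors score 1.0
    on equality and 0.5 otherwise."""
    if v_ref.std() == 0 or v_cent.std() == 0:
        return 1.0 if np.array_equal(v_ref, v_cent) else 0.5
    r = float(np.corrcoef(v_ref, v_cent)[0, 1])
    if sign_convention == "printed":
        return (1.0 - r) / 2.0
    return (1.0 + r) / 2.0


def pcc_neutrality(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    sequence_id: str = "",
    sign_convention: str = "plus",
) -> NeutralityResult:
    """Pearson-correlation neutrality: mean over mutants of (1 + r)/2
    where r correlates V(T) with V(centroid of the mutant's sample).

    ``sign_convention="printed"`` applies (1 - r)/2 instead, provided for
    comparison only (it scores perfectly retained structures 0).
    """
    if sign_convention not in ("plus", "printed"):
        raise ValueError("sign_convention must be 'plus' or 'printed'")
    if n_samples < 1:
        raise ValueError("PCC requires sampling (n_samples >= 1)")
    _, v_ref = structure_projections(t)
    mutants = mutant_neighbors(s)
    terms = np.empty(len(mutants))
    for rank, mutant in enumerate(mutants.mutants):
        sample = engine.sample_structures(mutant, n_samples, _mutant_seed(seed, rank))
        _, v_cent = structure_projections(centroid_structure(sample))
        terms[rank] = _pcc_term(v_ref, v_cent, sign_convention)
    profile = terms.reshape(-1, 3).mean(axis=1)
    return NeutralityResult(sequence_id, "PCC", float(terms.mean()), profile, n_samples, seed)


def sequence_neutrality(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    metric: str = "SEN",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    sequence_id: str = "",
    **kwargs,
) -> NeutralityResult:
    """Dispatch to one of the three metrics by name."""
    if metric == "SEN":
        return sen_neutrality(s, t, engine, n_samples, seed, sequence_id)
    if metric == "bp_distance":
        return bp_distance_neutrality(s, t, engine, sequence_id)
    if metric == "PCC":
        return pcc_neutrality(s, t, engine, n_samples, seed, sequence_id, **kwargs)
    raise ValueError(f"unknown metric '{metric}' (expected one of {METRICS})")


@dataclass(frozen=True)
class SkippedRow:
    sequence_id: str
    reason: str


def alignment_neutrality(
    alignment: StructuredAlignment,
    engine: FoldingEngine,
    metric: str = "SEN",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    **kwargs,
) -> tuple[list[NeutralityResult], list[SkippedRow]]:
    """Neutrality for every row of a structure-annotated alignment.

    Three-step workflow per row: (1) simultaneously degap sequence and
    consensus structure and drop non-canonical pairs; (2) enumerate the
    1-mutant neighborhood; (3) score it with the requested metric.  Rows
    with ambiguity codes or an empty filtered structure are skipped with a
    logged reason.  Row seeds are independent substreams of ``seed``.
    """
    if alignment.consensus is None:
        raise ValueError("alignment has no consensus structure (fold it first)")
    results: list[NeutralityResult] = []
    skips: list[SkippedRow] = []
    for idx in range(alignment.n_rows):
        name = alignment.rows[idx][0]
        try:
            _, seq, struct = alignment.degapped_row(idx)
        except AmbiguousSequenceError as exc:
            logger.warning("skipping row %s: %s", name, exc)
            skips.append(SkippedRow(name, f"ambiguous sequence: {exc}"))
            continue
        struct = canonical_filter(seq, struct)
        if len(struct) == 0 and metric in ("SEN",):
            logger.warning("skipping row %s: no canonical base pairs", name)
            skips.append(SkippedRow(name, "empty reference structure"))
            continue
        row_seed = int(
            np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0]
            % (2**31 - 1)
        )
        results.append(
            sequence_neutrality(
                seq, struct, engine, metric, n_samples, row_seed, name, **kwargs
            )
        )
    return results, skips
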