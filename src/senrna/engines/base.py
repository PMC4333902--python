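"""Folding-engine interface.

An engine turns sequences into structures: minimum-free-energy folding,
seedable Boltzmann sampling with replacement, exact base-pair
probabilities, alignment consensus folding and inverse folding.  Two
implementations ship with the package: a self-contained toy
nearest-pair model (exactly enumerable, used for oracle testing) and an
adapter for the ViennaRNA suite (production).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from ..structures import Sequence, SecondaryStructure, StructuredAlignment


class CapabilityError(RuntimeError):
    """Engine asked for an operation it does not support."""


class EngineError(RuntimeError):
    """Engine failed; carries engine diagnostics."""


@dataclass
class EnsembleSample:
    """N structures drawn with replacement from a sequence's Boltzmann
    ensemble.

    Stored compactly as an (N, L) partner matrix (``partners[s, i]`` is the
    partner of position i in sample s, or -1); ``structures`` materializes
    :class:`SecondaryStructure` objects on demand.
    """

    partners: np.ndarray  # (N, L) int array
    source_sequence: Sequence

    def __post_init__(self) -> None:
        if self.partners.ndim != 2 or self.partners.shape[1] != len(self.source_sequence):
            raise ValueError("partner matrix shape does not match sequence length")

    @property
    def n(self) -> int:
        return self.partners.shape[0]

    @cached_property
    def structures(self) -> list[SecondaryStructure]:
        out = []
        length = self.partners.shape[1]
        for row in self.partners:
            pairs = frozenset(
                (i, int(j)) for i, j in enumerate(row) if j > i
            )
            out.append(SecondaryStructure(pairs, length))
        return out

    @classmethod
    def from_structures(
        cls, structures: list[SecondaryStructure], source_sequence: Sequence
    ) -> "EnsembleSample":
        length = len(source_sequence)
        partners = np.full((len(structures), length), -1, dtype=np.int64)
        for s, struct in enumerate(structures):
            partners[s] = struct.partner_array()
        return cls(partners, source_sequence)


@dataclass(frozen=True)
class InverseFoldResult:
    """Outcome of an inverse-folding search: the designed sequence and the
    base-pair distance between its MFE structure and the target."""

    sequence: Sequence
    bp_distance: int


def _as_int_seed(seed) -> int:
    """Collapse an int or numpy SeedSequence to a 31-bit int (for engines
    whose RNG takes a plain integer)."""
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31 - 1))
    return int(seed) % (2**31 - 1)


def bp_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Number of base pairs present in exactly one of the two structures."""
    return len(a.pairs.symmetric_difference(b.pairs))


class FoldingEngine:
    """Abstract folding engine.  Subclasses set ``name``, ``version`` and
    ``capabilities`` and implement the methods they support."""

    name: str = "abstract"
    version: str = "0"
    temperature: float = 37.0  # °C; informational for the production engine
    capabilities: frozenset = frozenset()

    def _require(self, cap: str) -> None:
        if cap not in self.capabilities:
            raise CapabilityError(f"engine '{self.name}' lacks capability '{cap}'")

    def mfe_structure(self, s: Sequence) -> SecondaryStructure:
        raise NotImplementedError

    def mfe_energy(self, s: Sequence) -> float:
        raise NotImplementedError

    def sample_structures(self, s: Sequence, n: int, seed) -> EnsembleSample:
        raise NotImplementedError

    def exact_base_pair_probabilities(self, s: Sequence) -> np.ndarray:
        raise NotImplementedError

    def consensus_structure(self, alignment: StructuredAlignment) -> str:
        raise NotImplementedError

    def inverse_fold(
        self, t: SecondaryStructure, seed, max_bp_distance: int | None = None
    ) -> InverseFoldResult | None:
        raise NotImplementedError


def get_engine(name: str) -> FoldingEngine:
    """Engine factory for CLI/config use (``toy`` or ``vienna``)."""
    if name == "toy":
        from .toy import ToyEngine

        return ToyEngine()
    if name == "vienna":
        from .vienna import ViennaEngine

        return ViennaEngine()
    raise ValueError(f"unknown engine '{name}' (expected 'toy' or 'vienna')")
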