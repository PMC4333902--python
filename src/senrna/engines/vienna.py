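"""ViennaRNA adapter (production engine).

Wraps the RNA Python bindings: MFE and partition-function folding at
37 °C with suite defaults, stochastic backtracking (requires
``uniq_ML=1``), exact pair probabilities, alifold consensus folding and
RNAinverse-style inverse folding.  Engine name and version are recorded
in output provenance since results are engine-version dependent.
"""

from __future__ import annotations

import numpy as np

from ..structures import (
    Sequence,
    SecondaryStructure,
    StructuredAlignment,
    parse_dot_bracket,
)
from .base import (
    EngineError,
    EnsembleSample,
    FoldingEngine,
    InverseFoldResult,
    _as_int_seed,
    bp_distance,
)


def _rna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise EngineError("ViennaRNA Python bindings (module 'RNA') not available") from exc
    return RNA


class ViennaEngine(FoldingEngine):
    name = "vienna"
    capabilities = frozenset({"mfe", "sample", "exact_bpp", "consensus", "inverse"})

    def __init__(self, temperature: float = 37.0):
        RNA = _rna()
        self.version = RNA.__version__
        self.temperature = temperature

    def _md(self, uniq_ml: bool = False):
        RNA = _rna()
        md = RNA.md()
        md.temperature = self.temperature
        if uniq_ml:
            md.uniq_ML = 1
        return md

    def mfe_structure(self, s: Sequence) -> SecondaryStructure:
        RNA = _rna()
        fc = RNA.fold_compound(s.residues, self._md())
        ss, _ = fc.mfe()
        return parse_dot_bracket(ss)

    def mfe_energy(self, s: Sequence) -> float:
        RNA = _rna()
        fc = RNA.fold_compound(s.residues, self._md())
        _, e = fc.mfe()
        return float(e)

    def sample_structures(self, s: Sequence, n: int, seed) -> EnsembleSample:
        if n < 1:
            raise ValueError("n must be >= 1")
        RNA = _rna()
        RNA.init_rand(_as_int_seed(seed))
        fc = RNA.fold_compound(s.residues, self._md(uniq_ml=True))
        fc.pf()
        samples = fc.pbacktrack(n)
        structures = [parse_dot_bracket(ss) for ss in samples]
        if len(structures) != n:  # pragma: no cover
            raise EngineError(f"pbacktrack returned {len(structures)} of {n} samples")
        return EnsembleSample.from_structures(structures, s)

    def exact_base_pair_probabilities(self, s: Sequence) -> np.ndarray:
        RNA = _rna()
        fc = RNA.fold_compound(s.residues, self._md())
        fc.pf()
        raw = fc.bpp()  # (L+1) x (L+1), 1-based upper triangle
        L = len(s)
        p = np.zeros((L, L))
        for i in range(1, L + 1):
            for j in range(i + 1, L + 1):
                v = raw[i][j]
                if v > 0.0:
                    p[i - 1, j - 1] = v
                    p[j - 1, i - 1] = v
        return p

    def consensus_structure(self, alignment: StructuredAlignment) -> str:
        if alignment.n_rows < 2:
            raise EngineError("consensus folding needs at least 2 rows")
        RNA = _rna()
        rows = [row for _name, row in alignment.rows]
        fc = RNA.fold_compound(rows, self._md())
        ss, _ = fc.mfe()
        return ss

    def consensus_energy(self, alignment: StructuredAlignment) -> float:
        RNA = _rna()
        rows = [row for _name, row in alignment.rows]
        fc = RNA.fold_compound(rows, self._md())
        _, e = fc.mfe()
        return float(e)

    def inverse_fold(
        self, t: SecondaryStructure, seed, max_bp_distance: int | None = None
    ) -> InverseFoldResult | None:
        """RNAinverse adaptive search.  The target is not forced: success
        requires only that the achieved base-pair distance stays within
        ``max_bp_distance`` (default: half the target's pair count)."""
        RNA = _rna()
        if max_bp_distance is None:
            max_bp_distance = max(0, len(t) // 2)
        RNA.init_rand(_as_int_seed(seed))
        rng = np.random.default_rng(seed)
        start = "".join("ACGU"[rng.integers(4)] for _ in range(t.length))
        try:
            designed, _reported = RNA.inverse_fold(start, t.dot_bracket())
        except Exception as exc:  # pragma: no cover
            raise EngineError(f"RNAinverse failed: {exc}") from exc
        seq = Sequence(designed)
        dist = bp_distance(self.mfe_structure(seq), t)
        if dist <= max_bp_distance:
            return InverseFoldResult(seq, dist)
        return None
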