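"""Self-contained toy folding engine.

Energy model: per-pair energies GC/CG = -3, AU/UA = -2, GU/UG = -1
(arbitrary units), hairpin loop of at least 3 unpaired bases, no other
loop terms; Boltzmann factor exp(-E/kT) with kT = 1.  The model is
exactly enumerable, which makes it the reference engine for oracle tests
of ensemble sampling, pair probabilities and the neutrality metrics.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ..structures import Sequence, SecondaryStructure, StructuredAlignment, degap_pair
from . import _toykernels as k
from .base import (
    EngineError,
    EnsembleSample,
    FoldingEngine,
    InverseFoldResult,
    bp_distance,
)

_TOL = 1e-9


class ToyEngine(FoldingEngine):
    name = "toy"
    version = "1.0"
    capabilities = frozenset({"mfe", "sample", "exact_bpp", "consensus", "inverse"})

    # ---- MFE ------------------------------------------------------------

    def mfe_energy(self, s: Sequence) -> float:
        seq = k.encode(s.residues)
        return float(k.mfe_table(seq, k.ETAB)[0, len(s) - 1]) if len(s) > 1 else 0.0

    @staticmethod
    def _pair_energy_matrix(seq: np.ndarray) -> np.ndarray:
        """(L, L) matrix of pair energies with the loop rule applied
        (1e9 = disallowed)."""
        L = seq.shape[0]
        emat = np.full((L, L), 1e9)
        for i in range(L):
            for j in range(i + k.MIN_LOOP + 1, L):
                e = k.ETAB[seq[i], seq[j]]
                if np.isfinite(e):
                    emat[i, j] = e
        return emat

    @staticmethod
    def _reconstruct(F: np.ndarray, emat: np.ndarray) -> str:
        """Traceback of an MFE table; ties broken by lexicographically
        smallest dot-bracket string for cross-platform determinism."""
        L = F.shape[0]
        memo: dict[tuple[int, int], str] = {}

        def best(i: int, j: int) -> str:
            if i > j:
                return ""
            if i == j:
                return "."
            key = (i, j)
            if key in memo:
                return memo[key]
            target = F[i, j]
            candidates = []
            if abs(F[i + 1, j] - target) < _TOL:
                candidates.append("." + best(i + 1, j))
            for kk in range(i + k.MIN_LOOP + 1, j + 1):
                e = emat[i, kk]
                if e >= 1e8:
                    continue
                inner = F[i + 1, kk - 1] if i + 1 <= kk - 1 else 0.0
                right = F[kk + 1, j] if kk + 1 <= j else 0.0
                if abs(e + inner + right - target) < _TOL:
                    candidates.append("(" + best(i + 1, kk - 1) + ")" + best(kk + 1, j))
            result = min(candidates)
            memo[key] = result
            return result

        return best(0, L - 1)

    def mfe_structure(self, s: Sequence) -> SecondaryStructure:
        L = len(s)
        if L == 1:
            return SecondaryStructure(frozenset(), 1)
        seq = k.encode(s.residues)
        F = k.mfe_table(seq, k.ETAB)
        emat = self._pair_energy_matrix(seq)
        from ..structures import parse_dot_bracket

        return parse_dot_bracket(self._reconstruct(F, emat))

    # ---- ensemble -------------------------------------------------------

    @lru_cache(maxsize=64)
    def _inside(self, residues: str):
        seq = k.encode(residues)
        Z, Zb = k.inside(seq, k.ETAB)
        return seq, Z, Zb

    def partition_function(self, s: Sequence) -> float:
        _, Z, _ = self._inside(s.residues)
        return float(Z[0, len(s) - 1])

    def sample_structures(self, s: Sequence, n: int, seed) -> EnsembleSample:
        if n < 1:
            raise ValueError("n must be >= 1")
        L = len(s)
        if L == 1:
            return EnsembleSample(np.full((n, 1), -1, dtype=np.int64), s)
        seq, Z, Zb = self._inside(s.residues)
        rng = np.random.default_rng(seed)
        uniforms = rng.random(n * L)
        partners = k.sample_partners(seq, k.ETAB, Z, Zb, uniforms)
        return EnsembleSample(partners, s)

    def exact_base_pair_probabilities(self, s: Sequence) -> np.ndarray:
        L = len(s)
        if L == 1:
            return np.zeros((1, 1))
        seq, Z, Zb = self._inside(s.residues)
        return k.outside_bpp(seq, k.ETAB, Z, Zb)

    # ---- consensus (alifold-style averaged-energy folding) ---------------

    #: energy penalty per row that cannot form a canonical pair at a
    #: candidate consensus column pair
    NONCANONICAL_PENALTY = 1.0

    def consensus_structure(self, alignment: StructuredAlignment) -> str:
        """Alifold-style consensus: per-column-pair energies averaged over
        rows (rows unable to pair canonically are penalized; column pairs
        gapped in half the rows or with non-negative mean energy are
        disallowed), folded with the standard MFE recursion over columns."""
        if alignment.n_rows < 2:
            raise EngineError("consensus folding needs at least 2 rows")
        width = alignment.width
        n_rows = alignment.n_rows
        enc_rows = []
        for _name, row in alignment.rows:
            enc_rows.append(
                np.array([k.ENCODE.get(ch, -1) for ch in row], dtype=np.int64)
            )
        emat = np.full((width, width), 1e9)
        for i in range(width):
            for j in range(i + k.MIN_LOOP + 1, width):
                total, n_present = 0.0, 0
                for enc in enc_rows:
                    a, b = enc[i], enc[j]
                    if a < 0 or b < 0:
                        continue
                    n_present += 1
                    e = k.ETAB[a, b]
                    total += e if np.isfinite(e) else self.NONCANONICAL_PENALTY
                if n_present * 2 < n_rows:
                    continue
                mean = total / n_present
                if mean < 0:
                    emat[i, j] = mean
        F = k.mfe_table_from_matrix(emat)
        return self._reconstruct(F, emat)

    # ---- structure energy / inverse folding -----------------------------

    def structure_energy(self, s: Sequence, t: SecondaryStructure) -> float:
        """Energy of a given structure on a given sequence (canonical pairs
        only contribute)."""
        seq = k.encode(s.residues)
        e = 0.0
        for i, j in t.pairs:
            v = k.ETAB[seq[i], seq[j]]
            if np.isfinite(v):
                e += v
        return e

    def inverse_fold(
        self,
        t: SecondaryStructure,
        seed,
        max_bp_distance: int | None = None,
        n_restarts: int = 50,
        composition: np.ndarray | None = None,
    ) -> InverseFoldResult | None:
        """Adaptive-walk inverse folding: minimize the base-pair distance
        between the candidate's MFE structure and the target.

        Budget: ``n_restarts`` restarts of a 10·L-step walk.  The target
        need not be hit exactly; success requires the achieved distance
        <= ``max_bp_distance`` (default: half the target's pair count).
        Returns None when the budget is exhausted without success.

        ``composition`` (A,C,G,U frequencies) optionally biases the restart
        sequences toward a base composition, which raises the yield of
        composition-filtered backgrounds; the walk itself stays unbiased.
        """
        L = t.length
        if max_bp_distance is None:
            max_bp_distance = max(0, len(t) // 2)
        rng = np.random.default_rng(seed)
        partner = t.partner_array()
        best: InverseFoldResult | None = None
        for _restart in range(n_restarts):
            chars = self._restart_sequence(t, partner, composition, rng)
            current = Sequence("".join(chars))
            dist = bp_distance(self.mfe_structure(current), t)
            for _step in range(10 * L):
                if dist == 0:
                    break
                pos = int(rng.integers(L))
                old = current[pos]
                new = "ACGU".replace(old, "")[rng.integers(3)]
                cand = Sequence(
                    current.residues[:pos] + new + current.residues[pos + 1:]
                )
                cand_dist = bp_distance(self.mfe_structure(cand), t)
                # equal-distance moves accepted sparingly: enough to escape
                # plateaus without drifting the base composition
                if cand_dist < dist or (cand_dist == dist and rng.random() < 0.2):
                    current, dist = cand, cand_dist
            if best is None or dist < best.bp_distance:
                best = InverseFoldResult(current, dist)
            if best.bp_distance <= max_bp_distance:
                return best
        if best is not None and best.bp_distance <= max_bp_distance:
            return best
        return None

    @staticmethod
    def _restart_sequence(t, partner, composition, rng) -> list[str]:
        """A structure-compatible random start.  Without a composition
        target, loop bases and pair types are uniform; with one, bases are
        drawn without replacement from the target base counts (greedy
        canonical pair assignment), matching the composition as closely as
        the structure allows."""
        L = t.length
        chars = [""] * L
        pair_choices = [("G", "C"), ("C", "G"), ("A", "U"),
                        ("U", "A"), ("G", "U"), ("U", "G")]
        if composition is None:
            for i in range(L):
                if partner[i] == -1:
                    chars[i] = "ACGU"[rng.integers(4)]
                elif partner[i] > i:
                    chars[i], chars[partner[i]] = pair_choices[rng.integers(6)]
            return chars
        counts = {b: int(round(composition[k] * L)) for k, b in enumerate("ACGU")}
        while sum(counts.values()) < L:
            counts["ACGU"[int(rng.integers(4))]] += 1
        pair_positions = [i for i in range(L) if partner[i] > i]
        rng.shuffle(pair_positions)
        for i in pair_positions:
            scored = [
                (min(counts[a], 1) + min(counts[b], 1) + rng.random(), (a, b))
                for a, b in pair_choices
            ]
            a, b = max(scored)[1]
            chars[i], chars[partner[i]] = a, b
            counts[a] = max(0, counts[a] - 1)
            counts[b] = max(0, counts[b] - 1)
        loop_pool = [b for b, c in counts.items() for _ in range(c)]
        rng.shuffle(loop_pool)
        loop_positions = [i for i in range(L) if partner[i] == -1]
        for i, base in zip(loop_positions, loop_pool):
            chars[i] = base
        for i in loop_positions[len(loop_pool):]:
            chars[i] = "ACGU"[int(rng.integers(4))]
        return chars
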