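"""Numba kernels for the toy nearest-pair energy model.

Model: a structure's energy is the sum of its pair energies
(GC/CG = -3, AU/UA = -2, GU/UG = -1, arbitrary units), hairpin loops
enclose at least 3 unpaired bases, no other loop terms.  Boltzmann factor
exp(-E / kT) with kT = 1.

The dynamic programs are the standard inside (partition function),
MFE table, and outside (pair probabilities) recursions restricted to this
model.  Partition functions are unscaled doubles; with pair energies
>= -3 this overflows only beyond L ~ 450, far past the intended use.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_LOOP = 3  # minimum unpaired bases in a hairpin loop

# base encoding A=0, C=1, G=2, U=3
ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def pair_energy_table() -> np.ndarray:
    e = np.full((4, 4), np.inf)
    e[2, 1] = e[1, 2] = -3.0  # GC / CG
    e[0, 3] = e[3, 0] = -2.0  # AU / UA
    e[2, 3] = e[3, 2] = -1.0  # GU / UG
    return e


ETAB = pair_energy_table()


def encode(residues: str) -> np.ndarray:
    return np.array([ENCODE[c] for c in residues], dtype=np.int64)


@njit(cache=True)
def inside(seq, etab):
    """Partition function tables.

    Z[i, j]: unconstrained partition function of subsequence i..j
    (Z = 1 for empty/single segments).  Zb[i, j]: partition function
    given (i, j) paired; 0 if the pair is non-canonical or too close.
    """
    L = seq.shape[0]
    Z = np.ones((L, L))
    Zb = np.zeros((L, L))
    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            e = etab[seq[i], seq[j]]
            if j - i > MIN_LOOP and e < 1e8:
                inner = Z[i + 1, j - 1] if i + 1 <= j - 1 else 1.0
                Zb[i, j] = np.exp(-e) * inner
            total = Z[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if Zb[i, k] > 0.0:
                    right = Z[k + 1, j] if k + 1 <= j else 1.0
                    total += Zb[i, k] * right
            Z[i, j] = total
    return Z, Zb


@njit(cache=True)
def mfe_table(seq, etab):
    """F[i, j]: minimum energy over structures of subsequence i..j
    (0 for the empty structure)."""
    L = seq.shape[0]
    F = np.zeros((L, L))
    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            best = F[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = etab[seq[i], seq[k]]
                if e < 1e8:
                    inner = F[i + 1, k - 1] if i + 1 <= k - 1 else 0.0
                    right = F[k + 1, j] if k + 1 <= j else 0.0
                    v = e + inner + right
                    if v < best:
                        best = v
            F[i, j] = best
    return F


@njit(cache=True)
def mfe_table_from_matrix(emat):
    """MFE DP over an explicit (L, L) pair-energy matrix (entries >= 1e8
    mean "pair disallowed"); used for alifold-style consensus folding."""
    L = emat.shape[0]
    F = np.zeros((L, L))
    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            best = F[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = emat[i, k]
                if e < 1e8:
                    inner = F[i + 1, k - 1] if i + 1 <= k - 1 else 0.0
                    right = F[k + 1, j] if k + 1 <= j else 0.0
                    v = e + inner + right
                    if v < best:
                        best = v
            F[i, j] = best
    return F


@njit(cache=True)
def outside_bpp(seq, etab, Z, Zb):
    """Exact base-pair probability matrix via the outside recursion.

    Zout[a, b] sums structures on the complement of [a, b] compatible with
    (a, b) paired, split on the innermost enclosing pair (c, d).
    """
    L = seq.shape[0]
    Zout = np.zeros((L, L))
    P = np.zeros((L, L))
    Ztot = Z[0, L - 1]
    for span in range(L - 1, MIN_LOOP, -1):
        for a in range(L - span):
            b = a + span
            if Zb[a, b] == 0.0:
                continue
            left = Z[0, a - 1] if a >= 1 else 1.0
            right = Z[b + 1, L - 1] if b + 1 <= L - 1 else 1.0
            total = left * right
            for c in range(a):
                for d in range(b + 1, L):
                    if Zb[c, d] > 0.0 and Zout[c, d] > 0.0:
                        e = etab[seq[c], seq[d]]
                        l2 = Z[c + 1, a - 1] if c + 1 <= a - 1 else 1.0
                        r2 = Z[b + 1, d - 1] if b + 1 <= d - 1 else 1.0
                        total += np.exp(-e) * Zout[c, d] * l2 * r2
            Zout[a, b] = total
            p = Zb[a, b] * total / Ztot
            P[a, b] = p
            P[b, a] = p
    return P


@njit(cache=True)
def sample_partners(seq, etab, Z, Zb, uniforms):
    """Stochastic backtracking: draw N structures with replacement.

    ``uniforms`` is a flat array of pre-drawn U(0,1) variates, consumed one
    per backtracking decision (at most L per structure); its length fixes
    N = len(uniforms) // L.  Returns an (N, L) partner matrix.
    """
    L = seq.shape[0]
    n = uniforms.shape[0] // L
    partners = np.full((n, L), -1, dtype=np.int64)
    stack_i = np.empty(L + 2, dtype=np.int64)
    stack_j = np.empty(L + 2, dtype=np.int64)
    upos = 0
    for s in range(n):
        top = 0
        stack_i[0] = 0
        stack_j[0] = L - 1
        top = 1
        while top > 0:
            top -= 1
            i = stack_i[top]
            j = stack_j[top]
            while i < j:
                u = uniforms[upos] * Z[i, j]
                upos += 1
                acc = Z[i + 1, j]
                if u < acc:
                    i += 1
                    continue
                chosen = -1
                last_valid = -1
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if Zb[i, k] > 0.0:
                        last_valid = k
                        right = Z[k + 1, j] if k + 1 <= j else 1.0
                        acc += Zb[i, k] * right
                        if u < acc:
                            chosen = k
                            break
                if chosen == -1:
                    chosen = last_valid  # guard against float round-off
                if chosen == -1:
                    i += 1  # no pairing partner at all: i is unpaired
                    continue
                partners[s, i] = chosen
                partners[s, chosen] = i
                if chosen + 1 <= j:
                    stack_i[top] = chosen + 1
                    stack_j[top] = j
                    top += 1
                j = chosen - 1
                i = i + 1
    return partners
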