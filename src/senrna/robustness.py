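"""Mutational robustness: a sequence is robust when its neutrality exceeds
the mean neutrality of a background of inverse-folded,
composition-matched sequences sharing its reference structure.

The background for a sequence S with structure T is built from 10
inverse-fold seeds (each required to have mononucleotide-composition
Jensen-Shannon divergence < 0.01 to S), each seeding 10 neutral random
walks, for a target of 100 members.  A walk attempts 4L single-base
proposals; proposals at T-paired positions carry a compensatory mutation
restoring a canonical pair, and a proposal is accepted only when the MFE
structure is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .engines.base import FoldingEngine
from .neutrality import DEFAULT_N_SAMPLES, sequence_neutrality
from .structures import SecondaryStructure, Sequence

logger = logging.getLogger(__name__)

JSD_THRESHOLD = 0.01

#: compensatory partner rule: minimal symmetric completion of "a mutation
#: to G draws its partner uniformly from {C, U}"
COMPENSATORY = {"A": ("U",), "C": ("G",), "G": ("C", "U"), "U": ("A", "G")}


def jsd(comp_a: np.ndarray, comp_b: np.ndarray) -> float:
    """Jensen-Shannon divergence (log base 2, in [0, 1]) between two
    base-composition distributions over {A, C, G, U}."""
    comp_a = np.asarray(comp_a, dtype=float)
    comp_b = np.asarray(comp_b, dtype=float)
    for comp in (comp_a, comp_b):
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("compositions must be normalized length-4 distributions")
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(comp_a, comp_b, base=2) ** 2)


def _mutate(seq: str, pos: int, base: str, partner: int, rng) -> str:
    chars = list(seq)
    chars[pos] = base
    if partner >= 0:
        options = COMPENSATORY[base]
        chars[partner] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def neutral_walk(
    start: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    seed,
    reference: str = "self",
) -> Sequence:
    """Random walk along a neutral network.

    Exactly 4L proposals are attempted.  Each proposal mutates one random
    position to a random alternative base; a position paired in ``t``
    triggers a compensatory mutation at its partner.  The proposal is
    accepted iff the candidate's MFE structure equals the reference
    structure: the walk-start's own MFE (``reference="self"``, default) or
    the target ``t`` (``reference="target"``).
    """
    if reference not in ("self", "target"):
        raise ValueError("reference must be 'self' or 'target'")
    rng = np.random.default_rng(seed)
    partner = t.partner_array()
    ref_struct = engine.mfe_structure(start) if reference == "self" else t
    current = start
    length = len(start)
    for _step in range(4 * length):
        pos = int(rng.integers(length))
        old = current[pos]
        new = "ACGU".replace(old, "")[int(rng.integers(3))]
        cand_str = _mutate(current.residues, pos, new, int(partner[pos]), rng)
        cand = Sequence(cand_str)
        if engine.mfe_structure(cand).pairs == ref_struct.pairs:
            current = cand
    return current


@dataclass
class BackgroundSet:
    """Composition-matched background for one sequence; ``members`` is
    empty when inverse folding failed entirely (sequence omitted)."""

    parent: Sequence
    target_structure: SecondaryStructure
    members: list
    neutrality_values: np.ndarray | None = None
    jsd_threshold: float = JSD_THRESHOLD

    @property
    def omitted(self) -> bool:
        return not self.members


def background_set(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    seed: int = 0,
    n_seeds: int = 10,
    n_walks: int = 10,
    seed_attempts: int = 100,
    walk_attempts: int = 20,
    walk_reference: str = "self",
) -> BackgroundSet:
    """Generate the inverse-fold + neutral-walk background for (S, T).

    Each of ``n_seeds`` inverse-fold seeds must pass the JSD < 0.01
    composition filter against S (regenerated up to ``seed_attempts``
    times); each seed starts ``n_walks`` walks whose end points must also
    pass the filter (re-walked up to ``walk_attempts`` times, falling back
    to the seed itself).  Returns an omission marker (empty members) when
    no valid inverse-fold seed can be made at all.
    """
    comp_s = s.composition()
    members: list[Sequence] = []
    n_ok_seeds = 0
    for seed_idx in range(n_seeds):
        inv_seq = None
        for attempt in range(seed_attempts):
            sub = np.random.SeedSequence(seed, spawn_key=(seed_idx, attempt))
            try:
                result = engine.inverse_fold(t, sub, composition=comp_s)
            except TypeError:  # engine without composition biasing
                result = engine.inverse_fold(t, sub)
            if result is None:
                continue
            if jsd(comp_s, result.sequence.composition()) < JSD_THRESHOLD:
                inv_seq = result.sequence
                break
        if inv_seq is None:
            logger.warning("no JSD-passing inverse-fold seed (%d/%d)", seed_idx + 1, n_seeds)
            continue
        n_ok_seeds += 1
        for walk_idx in range(n_walks):
            member = inv_seq
            for attempt in range(walk_attempts):
                sub = np.random.SeedSequence(
                    seed, spawn_key=(seed_idx, walk_idx, attempt, 1)
                )
                cand = neutral_walk(inv_seq, t, engine, sub, walk_reference)
                if jsd(comp_s, cand.composition()) < JSD_THRESHOLD:
                    member = cand
                    break
            members.append(member)
    if n_ok_seeds == 0:
        return BackgroundSet(s, t, [])
    return BackgroundSet(s, t, members)


@dataclass
class RobustnessVerdict:
    """Robust iff wild-type neutrality strictly exceeds the background
    mean; ``omitted`` marks sequences with no usable background."""

    sequence_id: str
    metric: str
    wild_type_neutrality: float | None
    background_mean: float | None
    n_background: int
    robust: bool | None
    seed: int

    @property
    def omitted(self) -> bool:
        return self.robust is None


def is_robust(
    s: Sequence,
    t: SecondaryStructure,
    engine: FoldingEngine,
    metric: str = "SEN",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    sequence_id: str = "",
    background: BackgroundSet | None = None,
    **bg_kwargs,
) -> RobustnessVerdict:
    """Mutational-robustness verdict for one sequence.

    Wild-type and every background member are scored with the same metric
    against the same reference structure T; robust means strictly greater
    than the background mean.
    """
    if background is None:
        background = background_set(s, t, engine, seed=seed, **bg_kwargs)
    if background.omitted:
        return RobustnessVerdict(sequence_id, metric, None, None, 0, None, seed)
    wt = sequence_neutrality(
        s, t, engine, metric, n_samples, seed, sequence_id
    ).value
    values = np.array(
        [
            sequence_neutrality(
                member,
                t,
                engine,
                metric,
                n_samples,
                int(
                    np.random.SeedSequence(seed, spawn_key=(0xB6, idx)).generate_state(1)[0]
                    % (2**31 - 1)
                ),
                f"{sequence_id}/bg{idx}",
            ).value
            for idx, member in enumerate(background.members)
        ]
    )
    background.neutrality_values = values
    mean_bg = float(values.mean())
    return RobustnessVerdict(
        sequence_id, metric, wt, mean_bg, len(values), wt > mean_bg, seed
    )


def fraction_robust(verdicts: list[RobustnessVerdict]) -> float:
    """Fraction of robust sequences among the non-omitted verdicts."""
    usable = [v for v in verdicts if not v.omitted]
    if not usable:
        raise ValueError("all verdicts omitted; fraction undefined")
    return sum(1 for v in usable if v.robust) / len(usable)
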