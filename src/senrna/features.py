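"""Alignment features for structured-RNA classification, SVM evaluation
and the structure-disruption (eSDC) analysis.

The standard six alignment features are: the Z-score of the MFE (against
dinucleotide-shuffled nulls per row), the structure conservation index
(SCI), the mean Shannon entropy and mean mutual information of stem
columns, the mean pairwise identity, and the number of sequences.
Neutrality can be appended as a seventh feature or used alone.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decoys import dinucleotide_shuffle_sequence
from .engines.base import FoldingEngine
from .neutrality import DEFAULT_N_SAMPLES, alignment_neutrality
from .structures import (
    SecondaryStructure,
    Sequence,
    StructuredAlignment,
    canonical_filter,
    degap_pair,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "zscore_mfe",
    "sci",
    "mean_stem_entropy",
    "mean_stem_mi",
    "mean_pairwise_identity",
    "n_sequences",
)


def _degapped_rows(alignment: StructuredAlignment) -> list[Sequence]:
    rows = []
    for _name, row in alignment.rows:
        stripped = row.replace("-", "").replace(".", "")
        try:
            rows.append(Sequence(stripped))
        except ValueError:
            continue
    return rows


def zscore_mfe(
    alignment: StructuredAlignment,
    engine: FoldingEngine,
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Mean over rows of (MFE(row) - mean MFE(shuffles)) / sd(MFE(shuffles)),
    with dinucleotide-exact shuffled nulls (sample sd; sd = 0 contributes 0)."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    zs = []
    for seq in _degapped_rows(alignment):
        e = engine.mfe_energy(seq)
        null = np.array(
            [
                engine.mfe_energy(Sequence(dinucleotide_shuffle_sequence(seq.residues, rng)))
                for _ in range(n_shuffles)
            ]
        )
        sd = null.std(ddof=1)
        zs.append(0.0 if sd == 0 else (e - null.mean()) / sd)
    return float(np.mean(zs))


def structure_conservation_index(
    alignment: StructuredAlignment, engine: FoldingEngine
) -> float:
    """SCI = consensus folding energy / mean per-row MFE.

    The vienna engine reports the alifold consensus energy directly; the
    toy engine scores the consensus pairs realizable canonically in each
    row (mean over rows).  A zero mean row energy yields 0 with a warning.
    """
    rows = _degapped_rows(alignment)
    row_energies = np.array([engine.mfe_energy(seq) for seq in rows])
    mean_row = row_energies.mean()
    if mean_row == 0:
        logger.warning("SCI undefined (mean row MFE is 0); returning 0")
        return 0.0
    if hasattr(engine, "consensus_energy"):
        e_cons = engine.consensus_energy(alignment)
    else:
        if alignment.consensus is None:
            raise ValueError("alignment has no consensus structure")
        energies = []
        for _name, row in alignment.rows:
            try:
                seq, struct = degap_pair(row, alignment.consensus)
            except ValueError:
                continue
            struct = canonical_filter(seq, struct)
            energies.append(engine.structure_energy(seq, struct))
        e_cons = float(np.mean(energies))
    return float(e_cons / mean_row)


def _column_bases(alignment: StructuredAlignment, col: int) -> list[str]:
    return [row[col] for _n, row in alignment.rows if row[col] not in "-."]


def _entropy(counts: Counter) -> float:
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def mean_stem_entropy(
    alignment: StructuredAlignment, consensus: SecondaryStructure | None = None
) -> float:
    """Mean Shannon entropy (bits) of base frequencies over paired columns;
    gapped rows are excluded per column."""
    if consensus is None:
        consensus = alignment.consensus_structure()
    paired_cols = sorted({i for p in consensus.pairs for i in p})
    if not paired_cols:
        raise ValueError("consensus structure has no base pairs")
    ents = []
    for col in paired_cols:
        bases = _column_bases(alignment, col)
        if bases:
            ents.append(_entropy(Counter(bases)))
    return float(np.mean(ents))


def mean_stem_mutual_information(
    alignment: StructuredAlignment, consensus: SecondaryStructure | None = None
) -> float:
    """Mean mutual information (bits) over consensus column pairs, from the
    joint base frequencies of rows ungapped at both columns."""
    if consensus is None:
        consensus = alignment.consensus_structure()
    if not consensus.pairs:
        raise ValueError("consensus structure has no base pairs")
    mis = []
    for i, j in sorted(consensus.pairs):
        joint = Counter()
        for _n, row in alignment.rows:
            a, b = row[i], row[j]
            if a not in "-." and b not in "-.":
                joint[(a, b)] += 1
        if not joint:
            continue
        total = sum(joint.values())
        pa = Counter()
        pb = Counter()
        for (a, b), c in joint.items():
            pa[a] += c
            pb[b] += c
        mi = 0.0
        for (a, b), c in joint.items():
            pab = c / total
            mi += pab * math.log2(pab / ((pa[a] / total) * (pb[b] / total)))
        mis.append(mi)
    return float(np.mean(mis))


def mean_pairwise_identity(alignment: StructuredAlignment) -> float:
    """Mean over row pairs of the fraction of identical columns (columns
    gapped in both rows excluded; gap-vs-base counts as a mismatch)."""
    if alignment.n_rows < 2:
        raise ValueError("pairwise identity needs at least 2 rows")
    rows = [row for _n, row in alignment.rows]
    idents = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            same = used = 0
            for x, y in zip(rows[a], rows[b]):
                xg, yg = x in "-.", y in "-."
                if xg and yg:
                    continue
                used += 1
                if x == y:
                    same += 1
            idents.append(same / used if used else 1.0)
    return float(np.mean(idents))


@dataclass
class FeatureVector:
    """The 6 standard alignment features, plus optional neutrality."""

    zscore_mfe: float
    sci: float
    mean_stem_entropy: float
    mean_stem_mi: float
    mean_pairwise_identity: float
    n_sequences: int
    neutrality: float | None = None
    label: str | None = None  # "structured" or "other"

    def as_array(self, subset: tuple | None = None) -> np.ndarray:
        values = {
            "zscore_mfe": self.zscore_mfe,
            "sci": self.sci,
            "mean_stem_entropy": self.mean_stem_entropy,
            "mean_stem_mi": self.mean_stem_mi,
            "mean_pairwise_identity": self.mean_pairwise_identity,
            "n_sequences": float(self.n_sequences),
            "neutrality": self.neutrality,
        }
        names = subset if subset is not None else FEATURE_NAMES + (
            ("neutrality",) if self.neutrality is not None else ()
        )
        out = []
        for name in names:
            v = values[name]
            if v is None:
                raise ValueError(f"feature '{name}' not populated")
            out.append(v)
        return np.array(out)


def feature_vector(
    alignment: StructuredAlignment,
    engine: FoldingEngine,
    with_neutrality: bool = True,
    metric: str = "SEN",
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    n_shuffles: int = 100,
    label: str | None = None,
) -> FeatureVector:
    """Assemble the feature set for one alignment (neutrality = mean of the
    per-row alignment neutrality when requested)."""
    consensus = alignment.consensus_structure()
    neutrality = None
    if with_neutrality:
        results, _skips = alignment_neutrality(
            alignment, engine, metric, n_samples, seed
        )
        if not results:
            raise ValueError("no row yielded a neutrality value")
        neutrality = float(np.mean([r.value for r in results]))
    return FeatureVector(
        zscore_mfe=zscore_mfe(alignment, engine, n_shuffles, seed),
        sci=structure_conservation_index(alignment, engine),
        mean_stem_entropy=mean_stem_entropy(alignment, consensus),
        mean_stem_mi=mean_stem_mutual_information(alignment, consensus),
        mean_pairwise_identity=mean_pairwise_identity(alignment),
        n_sequences=alignment.n_rows,
        neutrality=neutrality,
        label=label,
    )


def train_evaluate_svm(
    positives: list[FeatureVector],
    negatives: list[FeatureVector],
    feature_subset: tuple | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[float, np.ndarray]:
    """RBF-kernel SVM with 10-fold stratified cross-validation.

    Features are z-scaled inside each training fold (pipeline); pooled
    out-of-fold decision values give the ROC curve and AUC.  Returns
    ``(auc, roc_points)`` with roc_points as an (n, 2) array of
    (FPR, TPR).
    """
    if len(positives) < n_folds or len(negatives) < n_folds:
        raise ValueError(f"each class needs at least {n_folds} examples")
    x = np.vstack(
        [fv.as_array(feature_subset) for fv in positives]
        + [fv.as_array(feature_subset) for fv in negatives]
    )
    y = np.array([1] * len(positives) + [0] * len(negatives))
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_predict(model, x, y, cv=cv, method="decision_function")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# structure disruption (eSDC)
# ---------------------------------------------------------------------------

def esdc(pcc: float, length: int) -> float:
    """Expected structure disruption coefficient: (1 - PCC) * sqrt(L)."""
    if not (-1.0 <= pcc <= 1.0):
        raise ValueError("pcc must be in [-1, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    return (1.0 - pcc) * math.sqrt(length)


def label_disrupting(scores: list[float]) -> list[bool]:
    """Mark the strict top 50% of eSDC scores as structure disrupting
    (descending sort, stable tie-break by input order)."""
    n_top = len(scores) // 2
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    labels = [False] * len(scores)
    for i in order[:n_top]:
        labels[i] = True
    return labels


def disruption_regression(
    neutrality_values: np.ndarray, disrupting: np.ndarray, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Single-predictor logistic regression of disruption labels on
    neutrality, reported as ROC/AUC on the fitted probabilities."""
    x = np.asarray(neutrality_values, dtype=float).reshape(-1, 1)
    y = np.asarray(disrupting).astype(int)
    model = LogisticRegression(random_state=seed)
    model.fit(x, y)
    probs = model.predict_proba(x)[:, 1]
    auc = float(roc_auc_score(y, probs))
    fpr, tpr, _ = roc_curve(y, probs)
    return auc, np.column_stack([fpr, tpr])
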