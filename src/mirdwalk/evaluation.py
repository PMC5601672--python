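"""Five-fold cross-validation of the ranking model, ROC curves and AUC.

Known association pairs are partitioned into k folds. For each fold the
network is rebuilt with the held-out pairs removed — they contribute neither
association edges nor seed mass — so no test information leaks into
training. For each query disease the held-out pairs are the positives and
every miRNA never associated with the disease in the full dataset is a
negative; miRNAs in the disease's training set are excluded from scoring.

TPR = TP / (TP + FN) and FPR = FP / (TN + FP), where TP counts positives
whose score is strictly higher than the threshold and FP counts negatives
scoring strictly higher. The ROC curve sweeps the threshold over all
distinct scores; its trapezoidal area equals the probability that a random
positive outscores a random negative, with half credit for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import AssociationSet, SimilarityMatrix
from .rdnet import build_association_matrix, build_hetero_network
from .walker import WalkConfig, random_walk, rank_candidates, seed_vector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Reproducible balanced partition of association pairs into k folds."""

    k: int
    seed: int
    fold_assignment: dict[tuple[str, str], int]

    def fold(self, i: int) -> frozenset[tuple[str, str]]:
        return frozenset(p for p, f in self.fold_assignment.items() if f == i)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class RocResult:
    """A full ROC step curve from (0, 0) to (1, 1) and its trapezoidal area."""

    fpr_points: tuple[float, ...]
    tpr_points: tuple[float, ...]
    auc: float


@dataclass(frozen=True)
class DiseaseFoldRecord:
    """Scores and held-out labels for one (disease, fold) evaluation."""

    disease_id: str
    fold: int
    scores: dict[str, float]
    positives: frozenset[str]

    @property
    def n_test_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.scores) - len(self.positives)


@dataclass(frozen=True)
class CvResult:
    """Per-disease and pooled cross-validation performance.

    ``per_disease_auc`` concatenates each disease's score/label lists across
    folds; ``pooled_auc`` concatenates everything into one global ROC. Both
    aggregations are kept because a single overall AUC and per-disease values
    answer different questions.
    """

    k: int
    seed: int
    records: tuple[DiseaseFoldRecord, ...]
    per_disease_auc: dict[str, float]
    pooled_auc: float
    skipped: tuple[tuple[str, int, str], ...] = field(default=())

    @property
    def mean_disease_auc(self) -> float:
        return float(np.mean(list(self.per_disease_auc.values())))


def kfold_split(assoc: AssociationSet, k: int, seed: int) -> FoldPlan:
    """Uniformly random balanced partition of pairs, reproducible from seed.

    Fold sizes differ by at most one; every pair lands in exactly one fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    pairs = sorted(assoc.pairs)
    if len(pairs) < k:
        raise ValueError(f"cannot split {len(pairs)} pairs into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    assignment = {pairs[idx]: int(pos % k) for pos, idx in enumerate(order)}
    return FoldPlan(k=k, seed=seed, fold_assignment=assignment)


def confusion_at_threshold(
    scores: Mapping[str, float], positives: Iterable[str], threshold: float
) -> ConfusionCounts:
    """Count TP/FP/TN/FN at one score threshold (strictly-greater rule)."""
    positives = set(positives)
    unknown = positives - set(scores)
    if unknown:
        raise ValueError(f"positives not among scored candidates: {sorted(unknown)}")
    tp = fp = tn = fn = 0
    for cand, s in scores.items():
        hit = s > threshold
        if cand in positives:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and fall-out FP/(TN+FP) as exact ratios."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("TPR undefined: TP + FN = 0 (no positives)")
    if c.FP + c.TN == 0:
        raise ZeroDivisionError("FPR undefined: TN + FP = 0 (no negatives)")
    return c.TP / (c.TP + c.FN), c.FP / (c.TN + c.FP)


def roc_curve(
    scores: Mapping[str, float], positives: Iterable[str]
) -> RocResult:
    """ROC step curve over all distinct score thresholds, AUC by trapezoid.

    Requires at least one positive and one negative. Tied scores advance the
    curve diagonally, which makes the trapezoidal area equal to
    P(score_pos > score_neg) + 0.5 * P(tie).
    """
    positives = set(positives)
    labels = np.array([c in positives for c in scores], dtype=bool)
    values = np.array(list(scores.values()), dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("ROC undefined: no positives")
    if n_neg == 0:
        raise ValueError("ROC undefined: no negatives")

    order = np.argsort(-values, kind="stable")
    values = values[order]
    labels = labels[order]
    # one curve point per distinct score value (threshold just below it)
    distinct = np.flatnonzero(np.diff(values)) if values.size > 1 else np.array([], int)
    cut = np.concatenate([distinct, [values.size - 1]])
    tp_cum = np.cumsum(labels)[cut]
    fp_cum = np.cumsum(~labels)[cut]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        fpr_points=tuple(fpr.tolist()), tpr_points=tuple(tpr.tolist()), auc=auc
    )


def _pooled_roc(records: Sequence[DiseaseFoldRecord]) -> RocResult:
    scores: dict[str, float] = {}
    positives: set[str] = set()
    for i, rec in enumerate(records):
        for m, s in rec.scores.items():
            key = f"{i}:{rec.disease_id}:{m}"
            scores[key] = s
            if m in rec.positives:
                positives.add(key)
    return roc_curve(scores, positives)


def evaluate_cv(
    MM: SimilarityMatrix,
    DD: SimilarityMatrix,
    assoc: AssociationSet,
    walk_config: WalkConfig | None = None,
    k: int = 5,
    seed: int = 0,
    diseases: Sequence[str] | None = None,
    tau: float = 0.0,
) -> CvResult:
    """Run k-fold cross-validation of the full ranking pipeline.

    For each fold the association matrix and seed vectors are rebuilt from
    the training pairs only (asserted: the rebuilt matrix is exactly zero at
    every held-out position). A disease is skipped in a fold, with a logged
    warning, when it has no training positive (nothing to seed from) or no
    held-out positive (nothing to measure).
    """
    if walk_config is None:
        walk_config = WalkConfig()
    plan = kfold_split(assoc, k=k, seed=seed)
    eval_diseases = list(diseases) if diseases is not None else list(DD.labels)
    unknown = set(eval_diseases) - set(DD.labels)
    if unknown:
        raise KeyError(f"diseases not in the similarity matrix: {sorted(unknown)}")

    # negatives are fixed by the full dataset: pairs never observed at all
    ever_associated = {d: assoc.mirnas_for(d) for d in eval_diseases}

    records: list[DiseaseFoldRecord] = []
    skipped: list[tuple[str, int, str]] = []
    for fold_idx in range(k):
        test_pairs = plan.fold(fold_idx)
        train_pairs = assoc.pairs - test_pairs
        train_assoc = AssociationSet(
            pairs=frozenset(train_pairs),
            mirna_labels=MM.labels,
            disease_labels=DD.labels,
        )
        A_train = build_association_matrix(train_assoc, MM.labels, DD.labels)
        # leakage guard: held-out pairs must not appear as network edges
        m_idx = {m: i for i, m in enumerate(MM.labels)}
        d_idx = {d: j for j, d in enumerate(DD.labels)}
        for m, d in test_pairs:
            assert A_train.values[m_idx[m], d_idx[d]] == 0.0, (
                f"leakage: held-out pair ({m}, {d}) present in training matrix"
            )
        network = build_hetero_network(MM, DD, A_train, tau=tau)

        for disease_id in eval_diseases:
            test_pos = {m for m, d in test_pairs if d == disease_id}
            train_pos = train_assoc.mirnas_for(disease_id)
            if not test_pos:
                continue
            if not train_pos:
                skipped.append((disease_id, fold_idx, "no training positives"))
                logger.warning(
                    "fold %d: skipping %s (no training positives)",
                    fold_idx, disease_id,
                )
                continue
            p0 = seed_vector(disease_id, train_assoc, network)
            steady = random_walk(network, p0, walk_config)
            ranking = rank_candidates(steady, disease_id, train_assoc, network)
            cand_scores = ranking.scores()
            # candidates = test positives + never-associated negatives; drop
            # miRNAs whose association with this disease sits in another fold
            keep = test_pos | (set(cand_scores) - ever_associated[disease_id])
            records.append(
                DiseaseFoldRecord(
                    disease_id=disease_id,
                    fold=fold_idx,
                    scores={m: cand_scores[m] for m in keep},
                    positives=frozenset(test_pos),
                )
            )

    if not records:
        raise ValueError("cross-validation produced no evaluable (disease, fold)")

    per_disease_auc: dict[str, float] = {}
    for disease_id in sorted({r.disease_id for r in records}):
        disease_records = [r for r in records if r.disease_id == disease_id]
        if all(r.n_neg == 0 for r in disease_records):
            continue
        per_disease_auc[disease_id] = _pooled_roc(disease_records).auc
    pooled_auc = _pooled_roc(records).auc

    return CvResult(
        k=k,
        seed=seed,
        records=tuple(records),
        per_disease_auc=per_disease_auc,
        pooled_auc=pooled_auc,
        skipped=tuple(skipped),
    )


def write_evaluation_report(result: CvResult, path: str | Path) -> None:
    """Write per-(disease, fold) rows plus per-disease and pooled AUC summary."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("disease\tfold\tauc\tn_test_pos\tn_neg\n")
        for rec in result.records:
            if rec.n_neg > 0 and rec.n_test_pos > 0:
                auc = roc_curve(rec.scores, rec.positives).auc
                fh.write(
                    f"{rec.disease_id}\t{rec.fold}\t{auc:.6f}"
                    f"\t{rec.n_test_pos}\t{rec.n_neg}\n"
                )
        for disease_id, auc in sorted(result.per_disease_auc.items()):
            fh.write(f"{disease_id}\tall\t{auc:.6f}\t-\t-\n")
        fh.write(f"POOLED\tall\t{result.pooled_auc:.6f}\t-\t-\n")


def write_roc_points(roc: RocResult, path: str | Path) -> None:
    """Dump ROC points as TSV for external plotting."""
    with Path(path).open("w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(roc.fpr_points, roc.tpr_points):
            fh.write(f"{x:.6f}\t{y:.6f}\n")
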