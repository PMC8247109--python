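"""Cross-validation harness and ranking metrics.

The evaluation protocol treats every experimentally verified association as
a positive sample and every unverified (disease, lncRNA) pair as a
candidate.  Verified pairs are split into k folds; for each fold the
held-out positives are *masked out of the association matrix* before the
interaction-profile kernels, feature vectors and training labels are built,
so nothing about a held-out link leaks into its own fold.  The test set is
the held-out positives plus all unverified candidates.

ROC points follow FPR = FP/(FP+TN), TPR = TP/(TP+FN) over descending score
thresholds; AUC is the trapezoidal area, which equals the Mann-Whitney
concordance probability with ties credited 1/2.  AUPR uses step-wise
precision-recall integration.  Threshold metrics (accuracy, F1, MCC) are
computed at score >= 0.5 on a balanced, seeded negative sample because they
are not meaningful on the fully imbalanced candidate grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bigan import NetworkConfig, TrainConfig, score_pairs, train
from .datatypes import AssociationMatrix, DiseaseOntology, SequenceSet, SimilarityMatrix
from .similarity import (
    build_pair_features,
    gip_similarities,
    integrate,
    semantic_similarity,
    sequence_similarity,
)

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "FoldMetrics",
    "CVReport",
    "make_folds",
    "roc_points",
    "auc",
    "aupr",
    "classification_metrics",
    "cross_validate",
]


@dataclass
class FoldPlan:
    """Assignment of verified pairs to k disjoint, near-equal folds."""

    k: int
    assignments: dict[tuple[str, str], int]
    seed: int

    def fold_pairs(self, fold: int) -> list[tuple[str, str]]:
        return [p for p, f in self.assignments.items() if f == fold]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")


def make_folds(
    positive_pairs: Sequence[tuple[str, str]], k: int, seed: int
) -> FoldPlan:
    """Shuffle positives with the given seed and deal them round-robin into k folds."""
    n = len(positive_pairs)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available positive pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = {
        tuple(positive_pairs[idx]): int(pos % k)
        for pos, idx in enumerate(order.tolist())
    }
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# curve metrics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("metric undefined: only one class present in labels")


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """ROC curve points (FPR, TPR), one per distinct threshold, from (0,0) to (1,1)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.nonzero(np.diff(s))[0]  # last index of each tied block
    idx = np.r_[distinct, len(s) - 1]
    pts = [(0.0, 0.0)]
    pts += [(fps[i] / n_neg, tps[i] / n_pos) for i in idx.tolist()]
    return pts


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC curve given as (FPR, TPR) points."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC from raw scores; equals Mann-Whitney concordance with ties at 1/2."""
    return auc(roc_points(scores, labels))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step integration.

    Sums precision x recall-increment over distinct thresholds in descending
    score order (average-precision form).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    n_pos = tps[-1]
    area = 0.0
    prev_recall = 0.0
    for i in distinct.tolist():
        precision = tps[i] / (tps[i] + fps[i])
        recall = tps[i] / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return float(area)


def pr_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """Precision-recall points (recall, precision) over distinct thresholds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    n_pos = tps[-1]
    return [(tps[i] / n_pos, tps[i] / (tps[i] + fps[i])) for i in distinct.tolist()]


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, F1, MCC) from a confusion table.

    F1 is 0 when precision + recall is 0; MCC is defined as 0 when its
    denominator vanishes.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return float(accuracy), float(f1), float(mcc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    fold: int
    auc: float
    aupr: float
    accuracy: float
    f1: float
    mcc: float
    roc: list[tuple[float, float]] = field(default_factory=list, repr=False)
    pr: list[tuple[float, float]] = field(default_factory=list, repr=False)


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    k: int
    seed: int
    folds: list[FoldMetrics]

    def _mean(self, attr: str) -> float:
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    @property
    def mean_auc(self) -> float:
        return self._mean("auc")

    @property
    def mean_aupr(self) -> float:
        return self._mean("aupr")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def mean_f1(self) -> float:
        return self._mean("f1")

    @property
    def mean_mcc(self) -> float:
        return self._mean("mcc")

    def to_dict(self, include_curves: bool = False) -> dict:
        folds = []
        for f in self.folds:
            d = {"fold": f.fold, "auc": f.auc, "aupr": f.aupr,
                 "accuracy": f.accuracy, "f1": f.f1, "mcc": f.mcc}
            if include_curves:
                d["roc"] = f.roc
                d["pr"] = f.pr
            folds.append(d)
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": folds,
            "mean": {
                "auc": self.mean_auc, "aupr": self.mean_aupr,
                "accuracy": self.mean_accuracy, "f1": self.mean_f1,
                "mcc": self.mean_mcc,
            },
        }

    def save_json(self, path: str | Path, include_curves: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_curves), indent=2))


def benchmark_configs(
    nd: int, nl: int, epochs: int = 25
) -> tuple[NetworkConfig, TrainConfig]:
    """Network and training settings scaled to a desk-size problem.

    The reference architecture compresses its 6137-dimensional input into a
    100-dimensional latent code (about 2%); for small synthetic problems the
    latent dimension is scaled to roughly 5% of nd + nl (at least 2), and
    the epoch count is raised so the optimiser still takes a few hundred
    mini-batch steps despite the smaller sample count.
    """
    input_dim = nd + nl
    latent = max(2, input_dim // 21)
    return NetworkConfig(input_dim=input_dim, latent_dim=latent), TrainConfig(
        epochs=epochs
    )


def prepare_fold_inputs(
    l_sim: SimilarityMatrix,
    d_sim: SimilarityMatrix,
    assoc: AssociationMatrix,
    heldout_pairs: Sequence[tuple[str, str]],
):
    """Build one fold's training and test inputs with held-out links masked.

    The held-out positives are removed from the association matrix *before*
    the interaction-profile kernels, integrated similarities, labels and
    training features are derived, so the fold's training inputs are
    identical whether or not the held-out links exist.

    Returns ``(train_features, test_features, test_labels)`` where the test
    set is the held-out positives (label 1) followed by all unverified
    candidates (label 0).
    """
    masked = assoc.masked(heldout_pairs)
    gkl, gkd = gip_similarities(masked)
    ls = integrate(l_sim, gkl)
    ds = integrate(d_sim, gkd)
    train_pairs = masked.positive_pairs()
    train_features = build_pair_features(ds, ls, masked, train_pairs)
    heldout = list(heldout_pairs)
    candidates = [
        (d, l)
        for d in assoc.disease_ids
        for l in assoc.lncrna_ids
        if assoc.label(d, l) == 0
    ]
    test_features = build_pair_features(ds, ls, masked, heldout + candidates)
    test_labels = np.r_[np.ones(len(heldout), dtype=int),
                        np.zeros(len(candidates), dtype=int)]
    return train_features, test_features, test_labels


def cross_validate(
    seqs: SequenceSet,
    onto: DiseaseOntology,
    assoc: AssociationMatrix,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
    mu: float = 0.5,
    keep_curves: bool = True,
) -> CVReport:
    """Full k-fold cross-validation of the adversarial scorer.

    Sequence and semantic similarities are association-independent and
    computed once; interaction-profile kernels, features and the model are
    rebuilt per fold from the masked matrix.  Per-fold seeds are spawned
    deterministically from ``seed``.
    """
    positives = assoc.positive_pairs()
    plan = make_folds(positives, k, seed)
    for d in assoc.disease_ids:
        onto.ensure_node(d)
    l_sim = sequence_similarity(seqs)
    d_sim = semantic_similarity(onto, assoc.disease_ids, mu=mu)
    nd, nl = assoc.shape
    if net_cfg is None:
        net_cfg = NetworkConfig(input_dim=nd + nl)
    base_train_cfg = train_cfg or TrainConfig()
    root = np.random.SeedSequence(seed)
    fold_seeds = root.generate_state(2 * k) % (2 ** 31)
    folds: list[FoldMetrics] = []
    for fold in range(k):
        heldout = plan.fold_pairs(fold)
        train_feats, test_feats, test_labels = prepare_fold_inputs(
            l_sim, d_sim, assoc, heldout
        )
        fold_cfg = TrainConfig(
            epochs=base_train_cfg.epochs,
            batch_size=base_train_cfg.batch_size,
            learning_rate=base_train_cfg.learning_rate,
            seed=int(fold_seeds[2 * fold]),
        )
        model = train(train_feats, net_cfg, fold_cfg)
        table = score_pairs(model, test_feats)
        scores = table["score"].to_numpy()
        roc = roc_points(scores, test_labels)
        fold_auc = auc(roc)
        fold_aupr = aupr(scores, test_labels)
        # balanced threshold metrics: |negatives| = |held-out positives|
        neg_rng = np.random.default_rng(int(fold_seeds[2 * fold + 1]))
        n_pos = len(heldout)
        neg_idx = n_pos + neg_rng.choice(
            len(test_labels) - n_pos, size=min(n_pos, len(test_labels) - n_pos),
            replace=False,
        )
        eval_idx = np.r_[np.arange(n_pos), neg_idx]
        pred = scores[eval_idx] >= 0.5
        truth = test_labels[eval_idx] == 1
        counts = ConfusionCounts(
            tp=int((pred & truth).sum()), fp=int((pred & ~truth).sum()),
            tn=int((~pred & ~truth).sum()), fn=int((~pred & truth).sum()),
        )
        acc, f1, mcc = classification_metrics(counts)
        folds.append(FoldMetrics(
            fold=fold, auc=fold_auc, aupr=fold_aupr,
            accuracy=acc, f1=f1, mcc=mcc,
            roc=roc if keep_curves else [],
            pr=pr_points(scores, test_labels) if keep_curves else [],
        ))
    return CVReport(k=k, seed=seed, folds=folds)
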