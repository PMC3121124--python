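"""Negative sampling, five-fold cross-validation, and ROC/AUC scoring.

The evaluation protocol: negatives are drawn uniformly from non-positive
protein pairs (as many as there are positives); the labeled pairs are split
into five stratified folds; each method is fit on four folds and scored on
the held-out fold, keeping only test pairs that contain at least one domain
pair with a parameter estimated from that fold's training data; AUC is
reported per fold for training and test sets, plus the average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataset import (
    Protein,
    ProteinPairLabel,
    canonical_pair,
    domain_pairs_of,
)

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 5


class SingleClassError(ValueError):
    """AUC is undefined when only one class is present."""


def roc_auc(
    scores: np.ndarray | list[float], labels: np.ndarray | list[int]
) -> tuple[float, np.ndarray]:
    """AUC (rank statistic, midrank ties) and the swept ROC curve.

    Returns ``(auc, curve)`` with ``curve`` an array of (fpr, tpr) rows.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("AUC undefined: only one class present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def sample_negatives(
    proteins: dict[str, Protein],
    positives: list[tuple[str, str]] | set[tuple[str, str]],
    n: int | None = None,
    seed: int = 0,
) -> list[ProteinPairLabel]:
    """Draw ``n`` label-0 pairs uniformly from the non-positive pairs.

    Sampling is without replacement over unordered distinct protein pairs of
    the loaded proteins, excluding the positive set; ``n`` defaults to the
    number of positives (balanced design). Deterministic given ``seed``.
    """
    ids = sorted(proteins)
    pos = {canonical_pair(a, b) for a, b in positives}
    n_total = len(ids) * (len(ids) - 1) // 2
    if n is None:
        n = len(pos)
    n_available = n_total - sum(1 for a, b in pos if a != b)
    if n_available < n:
        raise ValueError(
            f"only {n_available} non-positive pairs available, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    n_ids = len(ids)
    # rejection sampling over the (i < j) index triangle
    while len(chosen) < n:
        k = max(64, 2 * (n - len(chosen)))
        ii = rng.integers(0, n_ids, size=k)
        jj = rng.integers(0, n_ids, size=k)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            pair = canonical_pair(ids[i], ids[j])
            if pair in pos or pair in chosen:
                continue
            chosen.add(pair)
            if len(chosen) == n:
                break
    return [ProteinPairLabel(p, 0) for p in sorted(chosen)]


#: A method factory takes the training labels and returns a scorer mapping a
#: protein pair to Pr(interaction). MI scores etc. are closed over.
MethodFactory = Callable[[list[ProteinPairLabel]], Callable[[Protein, Protein], float]]


@dataclass
class EvaluationRun:
    """Per-fold and averaged train/test AUC for each method."""

    folds: list[np.ndarray]
    methods: list[str]
    train_auc: dict[str, list[float]]
    test_auc: dict[str, list[float]]  # NaN where undefined after filtering
    roc_points: dict[str, list[np.ndarray]] = field(default_factory=dict)
    seed: int = 0

    def mean_train_auc(self, method: str) -> float:
        return float(np.nanmean(self.train_auc[method]))

    def mean_test_auc(self, method: str) -> float:
        return float(np.nanmean(self.test_auc[method]))

    def to_dataframe(self) -> pd.DataFrame:
        """Table shaped like the published AUC tables: one row per fold plus
        the average; one (training, test) column pair per method."""
        rows = {}
        for k in range(len(self.folds)):
            rows[f"{k + 1}"] = {
                (m, split): vals[m][k]
                for m in self.methods
                for split, vals in (("training", self.train_auc), ("test", self.test_auc))
            }
        rows["average"] = {
            (m, split): float(np.nanmean(vals[m]))
            for m in self.methods
            for split, vals in (("training", self.train_auc), ("test", self.test_auc))
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        df.index.name = "iteration"
        return df


def cross_validate(
    proteins: dict[str, Protein],
    labels: list[ProteinPairLabel],
    methods: dict[str, MethodFactory],
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    collect_roc: bool = False,
) -> EvaluationRun:
    """Stratified k-fold cross-validation of the given method factories.

    Per fold, each method is fit on the training labels and scored on (a) the
    training pairs and (b) the test pairs that contain at least one domain
    pair also present in a training pair (the others carry no estimated
    parameter and are excluded). Folds whose filtered test labels are
    single-class get test AUC = NaN and are skipped in the average.
    """
    if len(labels) < n_folds:
        raise ValueError("need at least as many labeled pairs as folds")
    y = np.array([lab.label for lab in labels])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), y)]

    train_auc: dict[str, list[float]] = {m: [] for m in methods}
    test_auc: dict[str, list[float]] = {m: [] for m in methods}
    roc_points: dict[str, list[np.ndarray]] = {m: [] for m in methods}

    for k, test_idx in enumerate(folds):
        test_mask = np.zeros(len(labels), bool)
        test_mask[test_idx] = True
        train_labels = [lab for lab, t in zip(labels, test_mask) if not t]
        test_labels = [lab for lab, t in zip(labels, test_mask) if t]

        trained_dps = set()
        for lab in train_labels:
            a, b = lab.pair
            trained_dps |= domain_pairs_of(proteins[a], proteins[b])
        kept_test = [
            lab
            for lab in test_labels
            if domain_pairs_of(proteins[lab.pair[0]], proteins[lab.pair[1]])
            & trained_dps
        ]
        if len(kept_test) < len(test_labels):
            logger.info(
                "fold %d: filtered %d/%d test pairs with no trained parameter",
                k + 1, len(test_labels) - len(kept_test), len(test_labels),
            )

        y_train = [lab.label for lab in train_labels]
        y_test = [lab.label for lab in kept_test]
        for name, factory in methods.items():
            scorer = factory(train_labels)
            s_train = [
                scorer(proteins[lab.pair[0]], proteins[lab.pair[1]])
                for lab in train_labels
            ]
            if len(set(y_train)) < 2:
                train_auc[name].append(float("nan"))
            else:
                train_auc[name].append(roc_auc(s_train, y_train)[0])
            if len(set(y_test)) < 2:
                logger.warning(
                    "fold %d: test AUC undefined for %s (single-class after "
                    "filtering); recorded as missing", k + 1, name,
                )
                test_auc[name].append(float("nan"))
                continue
            s_test = [
                scorer(proteins[lab.pair[0]], proteins[lab.pair[1]])
                for lab in kept_test
            ]
            auc, curve = roc_auc(s_test, y_test)
            test_auc[name].append(auc)
            if collect_roc:
                roc_points[name].append(curve)

    return EvaluationRun(
        folds=folds,
        methods=list(methods),
        train_auc=train_auc,
        test_auc=test_auc,
        roc_points=roc_points if collect_roc else {},
        seed=seed,
    )
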