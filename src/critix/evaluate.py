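"""Gold-standard evaluation of gene lists and the classifier-importance baseline.

``confusion`` scores a predicted gene set against a gold-standard list
within an explicit gene universe (precision, recall, F1, accuracy).
``importance_genes`` reproduces the baseline that ranks genes by the
built-in feature importance of a random-forest or gradient-boosted
classifier trained to separate tumour from normal samples: classes are
balanced by downsampling, the data split 7:3, and the top ceil(1%) genes
by importance returned with the test weighted F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split

__all__ = ["ConfusionStats", "confusion", "importance_genes", "read_gene_list"]


@dataclass(frozen=True)
class ConfusionStats:
    """Confusion counts over a gene universe plus derived metrics.

    Metrics with a zero denominator are reported as NaN rather than 0, so
    an empty prediction cannot masquerade as a perfect one.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion(predicted, gold, universe) -> ConfusionStats:
    """Score a predicted gene set against a gold standard within a universe.

    TP = predicted & gold, FP = predicted - gold, FN = (gold & universe) -
    predicted, TN = the rest of the universe. Gold genes outside the
    universe are ignored.
    """
    predicted = set(predicted)
    gold = set(gold)
    universe = set(universe)
    outside = predicted - universe
    if outside:
        raise ValueError(f"predicted genes outside the universe: {sorted(outside)[:5]}")
    gold_in = gold & universe
    tp = len(predicted & gold_in)
    fp = len(predicted - gold_in)
    fn = len(gold_in - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionStats(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        accuracy=_ratio(tp + tn, tp + fp + fn + tn),
    )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one identifier per line, blanks ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def importance_genes(
    x: pd.DataFrame,
    labels,
    model: str = "random_forest",
    n_estimators: int = 500,
    train_frac: float = 0.7,
    fraction: float = 0.01,
    seed: int = 0,
):
    """Top genes by classifier feature importance, plus test weighted F1.

    Majority class is downsampled to the minority size (seeded), the
    balanced data split 7:3 stratified, a 500-tree classifier fitted with
    otherwise default settings, and the ceil(fraction * G) most important
    genes (impurity/gain importance) returned.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels must align with the sample axis")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < 4:
        raise ValueError(f"minority class has {counts.min()} samples; need at least 4")

    rng = np.random.default_rng(seed)
    n_min = counts.min()
    keep_rows: list[int] = []
    for cls in classes:
        rows = np.flatnonzero(labels == cls)
        if len(rows) > n_min:
            rows = rng.choice(rows, size=n_min, replace=False)
        keep_rows.extend(rows.tolist())
    keep_rows = sorted(keep_rows)
    xb = x.iloc[keep_rows]
    yb = labels[keep_rows]

    x_tr, x_te, y_tr, y_te = train_test_split(
        xb, yb, train_size=train_frac, stratify=yb, random_state=int(rng.integers(2**31))
    )
    if model == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    elif model == "gradient_boosting":
        from xgboost import XGBClassifier

        y_codes = {c: i for i, c in enumerate(classes)}
        y_tr = np.array([y_codes[v] for v in y_tr])
        y_te = np.array([y_codes[v] for v in y_te])
        clf = XGBClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(x_tr, y_tr)
    weighted_f1 = float(f1_score(y_te, clf.predict(x_te), average="weighted"))

    importances = pd.Series(clf.feature_importances_, index=x.columns)
    k = math.ceil(fraction * x.shape[1])
    top = importances.sort_values(ascending=False, kind="mergesort").index[:k]
    return list(top), weighted_f1
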