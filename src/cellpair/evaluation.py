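"""Stratified splitting, confusion-matrix reports and tidy score tables.

The report mirrors the standard caret-style summary: per-class sensitivity,
specificity, balanced accuracy and F1, overall accuracy with an exact
Clopper–Pearson 95% CI, the no-information rate (largest class frequency)
and its one-sided binomial p-value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SplitSpec",
    "ConfusionReport",
    "stratified_split",
    "confusion_report",
    "score_table",
]


@dataclasses.dataclass
class SplitSpec:
    train_fraction: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def stratified_split(ann: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint class-stratified train/test sample IDs.

    Per class the train count is floor(fraction * n), clamped so both
    partitions keep at least one sample.  Classes of size 1 are an error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    train: list[str] = []
    test: list[str] = []
    for cls, grp in ann.groupby("class_label", sort=True):
        ids = grp["sample_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        order = rng.permutation(len(ids))
        n_train = int(np.floor(spec.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in order[:n_train])
        test.extend(ids[i] for i in order[n_train:])
    assert not set(train) & set(test)
    return train, test


@dataclasses.dataclass
class ConfusionReport:
    per_class: pd.DataFrame  # sensitivity, specificity, balanced_accuracy, f1
    accuracy: float
    ci_low: float
    ci_high: float
    no_information_rate: float
    nir_pvalue: float
    counts: pd.DataFrame  # true x predicted
    foreign_predictions: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "accuracy": self.accuracy,
            "ci95": [self.ci_low, self.ci_high],
            "no_information_rate": self.no_information_rate,
            "nir_pvalue": self.nir_pvalue,
            "per_class": self.per_class.to_dict(orient="index"),
            "counts": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.counts.to_dict(orient="index").items()
            },
            "foreign_predictions": self.foreign_predictions,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    alpha = 1 - conf
    lo = 0.0 if k == 0 else scipy.stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else scipy.stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def confusion_report(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
) -> ConfusionReport:
    """Caret-style multiclass confusion report from aligned label vectors."""
    y_true = pd.Series(list(y_true), dtype=str)
    y_pred = pd.Series(list(y_pred), dtype=str)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must align")
    n = len(y_true)
    truth_classes = sorted(y_true.unique()) if classes is None else list(classes)
    foreign = sorted(set(y_pred) - set(truth_classes))
    all_labels = truth_classes + foreign
    counts = pd.crosstab(y_true, y_pred).reindex(
        index=truth_classes, columns=all_labels, fill_value=0
    )
    correct = int(sum(counts.at[c, c] for c in truth_classes if c in counts.columns))
    acc = correct / n
    lo, hi = _clopper_pearson(correct, n)
    nir = y_true.value_counts(normalize=True).max()
    pval = float(scipy.stats.binom.sf(correct - 1, n, nir))
    rows = {}
    yt = y_true.to_numpy()
    yp = y_pred.to_numpy()
    for cls in truth_classes:
        tp = int(((yt == cls) & (yp == cls)).sum())
        fn = int(((yt == cls) & (yp != cls)).sum())
        fp = int(((yt != cls) & (yp == cls)).sum())
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
        rows[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2,
            "f1": f1,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return ConfusionReport(
        per_class=per_class,
        accuracy=acc,
        ci_low=lo,
        ci_high=hi,
        no_information_rate=float(nir),
        nir_pvalue=pval,
        counts=counts,
        foreign_predictions=foreign,
    )


def score_table(scores, ann: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format per-sample score rows backing barplot/heatmap figures.

    One row per (sample, class) with the score, a ``top_class`` flag marking
    each sample's row-maximum (ties broken lexicographically and flagged),
    and the imputed-rule count.
    """
    df = scores.scores
    rows = []
    for sample, row in df.iterrows():
        mx = row.max()
        top_candidates = sorted(row.index[row == mx])
        top = top_candidates[0]
        tie = len(top_candidates) > 1
        for cls in df.columns:
            rows.append(
                {
                    "sample_id": sample,
                    "class_label": cls,
                    "score": float(row[cls]),
                    "top_class": cls == top,
                    "tie": tie,
                    "imputed_rule_count": int(scores.imputed_rule_counts[sample]),
                }
            )
    out = pd.DataFrame(rows)
    if ann is not None:
        out = out.merge(
            ann.rename(columns={"class_label": "true_class"})[
                ["sample_id", "true_class", "study_id"]
            ],
            on="sample_id",
            how="left",
        )
    return out.sort_values(["sample_id", "class_label"], kind="stable").reset_index(
        drop=True
    )
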