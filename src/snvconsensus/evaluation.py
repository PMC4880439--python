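"""Performance metrics and inter-tool comparison analyses.

Confusion-matrix metrics (accuracy, sensitivity, specificity, normalized
accuracy, MCC), rank-based AUC, pairwise Spearman correlation of raw
scores, prediction-agreement fractions, and the category-optimal versus
pooled ("general") threshold comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import as_deleterious_mask, normalized_accuracy, predict_binary
from .core_io import HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS, ScoreTable


@dataclass
class MetricsEntry:
    """One row of a metrics report: a (tool, category, split) cell."""

    name: str
    category: str
    split: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_missing: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_missing

    @property
    def accuracy(self) -> float:
        evaluated = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / evaluated if evaluated else math.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def normalized_accuracy(self) -> float:
        try:
            return normalized_accuracy(self.tp, self.fp, self.tn, self.fn)
        except ValueError:
            return math.nan

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = self.tp, self.fp, self.tn, self.fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / math.sqrt(denom)

    def as_dict(self) -> dict:
        return {
            "name": self.name, "category": self.category, "split": self.split,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_missing": self.n_missing, "n": self.n,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "normalized_accuracy": self.normalized_accuracy, "mcc": self.mcc,
        }


def confusion_metrics(predictions: Sequence[Optional[str]], labels: Sequence,
                      name: str = "", category: str = "", split: str = ""
                      ) -> MetricsEntry:
    """Confusion-matrix metrics for binary D/N predictions.

    ``None`` predictions (missing scores) are excluded from the counts but
    reported in ``n_missing``; undefined sub-metrics come back as NaN.
    """
    if len(predictions) == 0:
        raise ValueError("need at least one prediction")
    y = as_deleterious_mask(labels)
    tp = fp = tn = fn = miss = 0
    for pred, truth in zip(predictions, y):
        if pred is None:
            miss += 1
        elif pred == "D":
            tp += truth
            fp += not truth
        elif pred == "N":
            fn += truth
            tn += not truth
        else:
            raise ValueError(f"unknown prediction {pred!r}")
    return MetricsEntry(name=name, category=category, split=split,
                        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                        n_missing=miss)


def roc_auc(scores: Sequence[float], labels: Sequence,
            polarity: str = HIGHER_IS_DELETERIOUS) -> float:
    """AUC via the rank (Mann-Whitney) statistic with half-credit ties.

    Equals P(score_D > score_N) + 0.5 P(score_D = score_N) over all
    deleterious x neutral pairs, which is the trapezoidal area under the
    ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = as_deleterious_mask(labels)
    if polarity == LOWER_IS_DELETERIOUS:
        s = -s
    elif polarity != HIGHER_IS_DELETERIOUS:
        raise ValueError(f"unknown polarity {polarity!r}")
    n_d = int(y.sum())
    n_n = int(y.size - n_d)
    if n_d == 0 or n_n == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(s)  # average ranks handle ties
    r_d = ranks[y].sum()
    return float((r_d - n_d * (n_d + 1) / 2) / (n_d * n_n))


def pairwise_spearman(score_table: ScoreTable,
                      variants: Optional[Sequence] = None,
                      min_overlap: int = 3) -> pd.DataFrame:
    """Spearman rank correlation of raw scores between every tool pair.

    Computed on pairwise-complete entries; pairs with fewer than
    *min_overlap* shared variants come back NaN.  Diagonal is 1.
    """
    names = score_table.tool_names
    if variants is not None:
        keys = [v.key for v in variants if v.key in score_table.entries]
        mat = np.array([score_table.entries[k] for k in keys]) if keys \
            else np.empty((0, len(names)))
    else:
        mat = np.array(list(score_table.entries.values())) if score_table.entries \
            else np.empty((0, len(names)))
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            both = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j]) if mat.size else \
                np.zeros(0, dtype=bool)
            if both.sum() < min_overlap:
                rho = math.nan
            else:
                rho = stats.spearmanr(mat[both, i], mat[both, j]).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def agreement_matrix(predictions_by_tool: Mapping[str, Sequence[Optional[str]]],
                     labels: Sequence) -> pd.DataFrame:
    """Pairwise prediction-agreement fractions.

    For each tool pair, over variants both tools predicted: the fractions
    of cases where both were correct, both wrong, and where they
    disagreed.  The three fractions sum to 1; pairs with no co-predicted
    variant come back NaN.
    """
    y = as_deleterious_mask(labels)
    truth = np.where(y, "D", "N")
    names = sorted(predictions_by_tool)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa = predictions_by_tool[a]
            pb = predictions_by_tool[b]
            both_correct = both_wrong = discordant = total = 0
            for x, z, t in zip(pa, pb, truth):
                if x is None or z is None:
                    continue
                total += 1
                if x == z:
                    if x == t:
                        both_correct += 1
                    else:
                        both_wrong += 1
                else:
                    discordant += 1
            if total == 0:
                rows.append({"tool_a": a, "tool_b": b, "both_correct": math.nan,
                             "both_wrong": math.nan, "discordant": math.nan,
                             "n": 0})
            else:
                rows.append({"tool_a": a, "tool_b": b,
                             "both_correct": both_correct / total,
                             "both_wrong": both_wrong / total,
                             "discordant": discordant / total, "n": total})
    return pd.DataFrame(rows)


def compare_thresholds(scores: Sequence[float], labels: Sequence,
                       general_threshold: float, category_threshold: float,
                       polarity: str = HIGHER_IS_DELETERIOUS) -> dict:
    """Normalized accuracy under a pooled ("general") threshold versus a
    category-optimal threshold, and their difference."""
    s = list(map(float, scores))
    out = {}
    for key, thr in (("general", general_threshold),
                     ("category", category_threshold)):
        preds = [predict_binary(x, thr, polarity) for x in s]
        out[key] = confusion_metrics(preds, labels).normalized_accuracy
    out["gain"] = out["category"] - out["general"]
    return out


def metrics_report(entries: Sequence[MetricsEntry]) -> pd.DataFrame:
    """Tabulate metric entries, appending micro- (pooled counts) and
    macro- (category-averaged) "Overall" rows per (name, split)."""
    df = pd.DataFrame([e.as_dict() for e in entries])
    overall = []
    for (name, split), grp in df.groupby(["name", "split"]):
        micro = MetricsEntry(name=name, category="Overall (micro)", split=split,
                             tp=int(grp.tp.sum()), fp=int(grp.fp.sum()),
                             tn=int(grp.tn.sum()), fn=int(grp.fn.sum()),
                             n_missing=int(grp.n_missing.sum()))
        macro = micro.as_dict()
        macro["category"] = "Overall (macro)"
        for col in ("accuracy", "sensitivity", "specificity",
                    "normalized_accuracy", "mcc"):
            macro[col] = float(grp[col].mean())
        overall.append(micro.as_dict())
        overall.append(macro)
    return pd.concat([df, pd.DataFrame(overall)], ignore_index=True)
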