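"""Confidence-weighted majority-vote consensus over calibrated tools.

Each calibrated tool casts a binary vote (deleterious/neutral) with a 0-99
confidence.  The consensus score is the confidence-weighted mean of the
signed votes, normalized by the total weight so it lies in [-1, +1]
regardless of how many tools had a score available.  The consensus score is
then treated like any raw tool score: a consensus threshold is learned and
a consensus calibration curve fitted, so the final consensus prediction
also carries a uniform 0-99 confidence.

Because weak tools can drag the vote down, the tool subset entering the
consensus is chosen per variant category by exhaustively evaluating every
subset of size >= 2 on training data and keeping the one with the highest
training normalized accuracy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import calibration
from .core_io import (
    HIGHER_IS_DELETERIOUS,
    ConfigurationError,
    ModelBundle,
    ScoreTable,
    Variant,
)
from .calibration import (
    CalibrationCurve,
    ThresholdModel,
    fit_confidence_curve,
    optimize_threshold,
    transform_score,
)

Vote = tuple[str, int]  # ("D"|"N", confidence 0-99)


def consensus_score(votes: Sequence[Vote]) -> float:
    """Confidence-weighted majority vote, normalized to [-1, +1].

    With v_i = +1 for a deleterious vote and -1 for neutral, and weights
    w_i = confidence_i / 100, the score is sum(w_i v_i) / sum(w_i); an
    all-zero-confidence vote set scores 0.  A tie (score exactly 0) is
    called deleterious downstream.
    """
    if len(votes) == 0:
        raise ValueError("consensus requires at least one vote")
    num = 0.0
    den = 0.0
    for pred, conf in votes:
        if conf < 0:
            raise ValueError("confidences must be non-negative")
        if pred not in ("D", "N"):
            raise ValueError(f"unknown vote {pred!r}")
        w = conf / 100.0
        num += w if pred == "D" else -w
        den += w
    if den == 0.0:
        return 0.0
    return num / den


@dataclass
class ConsensusModel:
    """Per-category consensus: selected tools, threshold and curve."""

    category: str
    tools: list[str]
    consensus_threshold: float
    consensus_curve: CalibrationCurve
    training_normalized_accuracy: float = math.nan
    best_single_tool: Optional[str] = None
    best_single_tool_accuracy: float = math.nan
    #: (tools, training normalized accuracy) for every evaluated subset
    subset_report: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tools:
            raise ValueError("consensus tool subset must be non-empty")

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "tools": list(self.tools),
            "consensus_threshold": float(self.consensus_threshold),
            "consensus_curve": self.consensus_curve.to_dict(),
            "training_normalized_accuracy": float(self.training_normalized_accuracy),
            "best_single_tool": self.best_single_tool,
            "best_single_tool_accuracy": float(self.best_single_tool_accuracy),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusModel":
        return cls(
            category=d["category"],
            tools=list(d["tools"]),
            consensus_threshold=float(d["consensus_threshold"]),
            consensus_curve=CalibrationCurve.from_dict(d["consensus_curve"]),
            training_normalized_accuracy=float(d["training_normalized_accuracy"]),
            best_single_tool=d.get("best_single_tool"),
            best_single_tool_accuracy=float(d.get("best_single_tool_accuracy", "nan")),
        )


@dataclass
class Prediction:
    """Per-variant output: tool votes plus the calibrated consensus."""

    variant: Variant
    category: Optional[str]
    tool_votes: dict  # tool -> Vote (only tools with a score available)
    consensus_score: Optional[float]
    consensus_prediction: Optional[str]
    consensus_confidence: Optional[int]
    no_scores: bool = False


def _subset_scores(subset: Sequence[str],
                   votes_by_tool: Mapping[str, Sequence[Optional[Vote]]],
                   labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Training consensus scores for one tool subset.

    Variants with no available vote among the subset's tools are excluded
    (they would also be unanswerable at prediction time).
    """
    n = len(labels)
    mask = calibration.as_deleterious_mask(labels)
    scores: list[float] = []
    kept: list[bool] = []
    for i in range(n):
        votes = [votes_by_tool[t][i] for t in subset if votes_by_tool[t][i] is not None]
        if votes:
            scores.append(consensus_score(votes))
            kept.append(True)
        else:
            kept.append(False)
    return np.asarray(scores), mask[np.asarray(kept, dtype=bool)]


def calibrate_consensus(cons_scores: Sequence[float], labels: Sequence,
                        n_bins: int = calibration.DEFAULT_N_BINS,
                        window: int = calibration.DEFAULT_WINDOW,
                        category: str = "") -> tuple[float, float, CalibrationCurve]:
    """Learn a threshold and calibration curve for consensus scores.

    Identical contracts to threshold optimization and curve fitting for a
    single tool, with the consensus score treated as a higher-is-deleterious
    raw score.  Returns ``(threshold, training normalized accuracy, curve)``.
    """
    arr = np.asarray(cons_scores, dtype=float)
    if arr.size and np.all(arr == arr[0]):
        raise ValueError("consensus scores are constant; no threshold can "
                         "separate the classes")
    thr, nacc = optimize_threshold(cons_scores, labels, HIGHER_IS_DELETERIOUS)
    curve = fit_confidence_curve(cons_scores, labels, thr, n_bins=n_bins,
                                 window=window, tool="consensus",
                                 category=category)
    return thr, nacc, curve


def select_consensus_subset(votes_by_tool: Mapping[str, Sequence[Optional[Vote]]],
                            labels: Sequence, category: str,
                            n_bins: int = calibration.DEFAULT_N_BINS,
                            window: int = calibration.DEFAULT_WINDOW
                            ) -> ConsensusModel:
    """Choose the per-category tool subset maximizing training accuracy.

    Every subset of size >= 2 is evaluated: its training consensus scores
    are computed, a consensus threshold re-optimized, and the training
    normalized accuracy at that threshold recorded.  Ties break toward
    fewer tools, then lexicographic tool names.  The best single tool is
    recorded for reporting but never selected as the consensus.
    """
    tools = sorted(votes_by_tool)
    if len(tools) < 2:
        raise ConfigurationError("subset selection needs >= 2 calibrated tools")
    mask = calibration.as_deleterious_mask(labels)

    # best single tool, from its own binary votes
    best_single, best_single_acc = None, -1.0
    for t in tools:
        votes = votes_by_tool[t]
        idx = [i for i, v in enumerate(votes) if v is not None]
        if not idx:
            continue
        pred_d = np.array([votes[i][0] == "D" for i in idx])
        lab = mask[idx]
        tp = int((pred_d & lab).sum())
        fn = int((~pred_d & lab).sum())
        tn = int((~pred_d & ~lab).sum())
        fp = int((pred_d & ~lab).sum())
        if tp + fn == 0 or tn + fp == 0:
            continue
        acc = calibration.normalized_accuracy(tp, fp, tn, fn)
        if acc > best_single_acc:
            best_single, best_single_acc = t, acc

    report: list[tuple[tuple[str, ...], float]] = []
    best_key = None
    best = None  # (subset, scores, labels, thr, nacc)
    for size in range(2, len(tools) + 1):
        for subset in itertools.combinations(tools, size):
            scores, lab = _subset_scores(subset, votes_by_tool, labels)
            if scores.size < 4 or lab.all() or not lab.any():
                continue
            try:
                thr, nacc = optimize_threshold(scores, lab)
            except ValueError:
                continue
            report.append((subset, nacc))
            key = (-nacc, len(subset), subset)  # max nacc, fewer tools, lexicographic
            if best_key is None or key < best_key:
                best_key = key
                best = (subset, scores, lab, thr, nacc)
    if best is None:
        raise ValueError(f"no evaluable tool subset for category {category!r}")
    subset, scores, lab, thr, nacc = best
    curve = fit_confidence_curve(scores, lab, thr, n_bins=n_bins, window=window,
                                 tool="consensus", category=category)
    return ConsensusModel(
        category=category, tools=list(subset), consensus_threshold=thr,
        consensus_curve=curve, training_normalized_accuracy=nacc,
        best_single_tool=best_single, best_single_tool_accuracy=best_single_acc,
        subset_report=report,
    )


def tool_votes_for_training(dataset_scores: ScoreTable,
                            variants: Sequence[Variant],
                            thresholds: ThresholdModel,
                            curves: Mapping, category: str
                            ) -> dict[str, list[Optional[Vote]]]:
    """Calibrated per-variant votes for every tool with a curve in *category*."""
    votes: dict[str, list[Optional[Vote]]] = {}
    for (tool, cat), curve in curves.items():
        if cat != category:
            continue
        pol = thresholds.polarity(tool)
        col: list[Optional[Vote]] = []
        for v in variants:
            raw = dataset_scores.get(v, tool)
            col.append(None if math.isnan(raw) else transform_score(curve, raw, pol))
        votes[tool] = col
    return votes


def train_bundle(train_datasets: Mapping[str, "object"],
                 tool_specs: Sequence, n_bins: int = calibration.DEFAULT_N_BINS,
                 window: int = calibration.DEFAULT_WINDOW,
                 metadata: Optional[dict] = None) -> ModelBundle:
    """Train thresholds, curves and consensus models for every category.

    ``train_datasets`` maps category -> LabeledDataset (split="train").
    Tools without both classes scored in a category are skipped for that
    category.
    """
    thresholds = ThresholdModel()
    curves: dict = {}
    consensus: dict = {}
    for category, ds in sorted(train_datasets.items()):
        labels_all = [v.label for v in ds.variants]
        for spec in tool_specs:
            raws, labs = [], []
            for v, lab in zip(ds.variants, labels_all):
                raw = ds.scores.get(v, spec.name)
                if not math.isnan(raw):
                    raws.append(raw)
                    labs.append(lab)
            if len(raws) < 4:
                continue
            try:
                thr, nacc = optimize_threshold(raws, labs, spec.polarity)
            except ValueError:
                continue
            thresholds.set(spec.name, category, thr, nacc, spec.polarity)
            curves[(spec.name, category)] = fit_confidence_curve(
                raws, labs, thr, n_bins=n_bins, window=window,
                tool=spec.name, category=category,
            )
        votes = tool_votes_for_training(ds.scores, ds.variants, thresholds,
                                        curves, category)
        if len(votes) >= 2:
            consensus[category] = select_consensus_subset(
                votes, labels_all, category, n_bins=n_bins, window=window)
    bundle = ModelBundle(thresholds=thresholds, curves=curves,
                         consensus=consensus, metadata=metadata or {})
    bundle.validate()
    return bundle


def predict(variants: Sequence[Variant], score_table: ScoreTable,
            bundle: ModelBundle,
            categories: Optional[Mapping[tuple, str]] = None
            ) -> list[Prediction]:
    """Run the full calibrated-consensus pipeline on new variants.

    Categories are taken from ``categories`` (variant key -> category) when
    given, else from each variant's ``category`` attribute.  Votes are cast
    only by the category's selected tool subset, over whichever of those
    tools have a score; a variant with no available score is flagged
    ``no_scores`` instead of being dropped.
    """
    preds: list[Prediction] = []
    for v in variants:
        cat = categories.get(v.key) if categories is not None else v.category
        if cat is None:
            raise ValueError(f"no category available for variant {v.key}")
        cm = bundle.consensus.get(cat)
        if cm is None:
            raise ConfigurationError(f"model bundle has no consensus for "
                                     f"category {cat!r}")
        votes: dict[str, Vote] = {}
        for tool in cm.tools:
            raw = score_table.get(v, tool)
            if math.isnan(raw):
                continue
            curve = bundle.curves[(tool, cat)]
            votes[tool] = transform_score(curve, raw, bundle.thresholds.polarity(tool))
        if not votes:
            preds.append(Prediction(variant=v, category=cat, tool_votes={},
                                    consensus_score=None,
                                    consensus_prediction=None,
                                    consensus_confidence=None, no_scores=True))
            continue
        cs = consensus_score(list(votes.values()))
        cpred, cconf = transform_score(cm.consensus_curve, cs,
                                       HIGHER_IS_DELETERIOUS)
        preds.append(Prediction(variant=v, category=cat, tool_votes=votes,
                                consensus_score=cs, consensus_prediction=cpred,
                                consensus_confidence=cconf))
    return preds
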