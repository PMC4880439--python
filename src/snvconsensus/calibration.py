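"""Decision-threshold optimization and binned-accuracy score calibration.

External variant-effect predictors emit raw scores on incomparable scales.
This module learns, per tool and per variant category:

1. the decision threshold that maximizes *normalized accuracy* (the mean of
   sensitivity and specificity) on training data, and
2. a transform from raw score to a uniform 0-99 confidence value, estimated
   by sorting training scores into equal-size bins, computing the observed
   fraction of deleterious labels per bin, and smoothing the fractions with
   a centered moving average.  Two sides of the transform serve deleterious
   and neutral predictions: a deleterious call at score *s* is assigned the
   (smoothed, interpolated) fraction-deleterious at *s*; a neutral call is
   assigned its complement.

Defaults of 66 bins and an 11-bin smoothing window suit training sets of a
few thousand variants; for smaller sets the bin count shrinks so every bin
keeps at least two points, and the smoothing window truncates symmetrically
at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    DELETERIOUS,
    HIGHER_IS_DELETERIOUS,
    LOWER_IS_DELETERIOUS,
    NEUTRAL,
)

DEFAULT_N_BINS = 66
DEFAULT_WINDOW = 11


def as_deleterious_mask(labels: Sequence) -> np.ndarray:
    """Convert labels given as D/N, deleterious/neutral, or 0/1 to a bool mask."""
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            if lab in ("D", DELETERIOUS):
                out[i] = True
            elif lab in ("N", NEUTRAL):
                out[i] = False
            else:
                raise ValueError(f"unknown label {lab!r}")
        else:
            out[i] = bool(lab)
    return out


def normalized_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """Balanced accuracy: mean of sensitivity and specificity.

    Undefined (raises ``ValueError``) when either class is absent.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("normalized accuracy undefined when a class is absent")
    return (tp / (tp + fn) + tn / (tn + fp)) / 2


def _candidate_thresholds(sorted_unique: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus one candidate
    below the minimum and one above the maximum."""
    mids = (sorted_unique[:-1] + sorted_unique[1:]) / 2.0
    lo = sorted_unique[0] - 1.0
    hi = sorted_unique[-1] + 1.0
    return np.concatenate(([lo], mids, [hi]))


def optimize_threshold(scores: Sequence[float], labels: Sequence,
                       polarity: str = HIGHER_IS_DELETERIOUS
                       ) -> tuple[float, float]:
    """Find the decision threshold maximizing normalized accuracy.

    The prediction rule is "deleterious iff score >= threshold" for
    ``higher_is_deleterious`` tools and the mirror rule (<=) otherwise.
    Candidates are midpoints between consecutive distinct scores plus one
    candidate outside each end of the range; ties in normalized accuracy
    break toward the more sensitive threshold.

    Returns ``(threshold, normalized_accuracy_at_threshold)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite (exclude missing upstream)")
    y = as_deleterious_mask(labels)
    if y.size != s.size:
        raise ValueError("scores and labels differ in length")
    n_d = int(y.sum())
    n_n = int(y.size - n_d)
    if n_d == 0 or n_n == 0:
        raise ValueError("both classes must be present to optimize a threshold")

    flip = polarity == LOWER_IS_DELETERIOUS
    if polarity not in (HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS):
        raise ValueError(f"unknown polarity {polarity!r}")
    work = -s if flip else s

    d_sorted = np.sort(work[y])
    n_sorted = np.sort(work[~y])
    cands = _candidate_thresholds(np.unique(work))
    # deleterious iff work-score >= t
    tp = n_d - np.searchsorted(d_sorted, cands, side="left")
    tn = np.searchsorted(n_sorted, cands, side="left")
    nacc = (tp / n_d + tn / n_n) / 2.0
    # candidates ascend; the first argmax is the lowest (most sensitive)
    # threshold on the working scale
    best = int(np.argmax(nacc))
    thr = float(cands[best])
    if flip:
        thr = -thr
    return thr, float(nacc[best])


@dataclass
class ThresholdModel:
    """Learned (tool, category) -> decision threshold map."""

    entries: dict = field(default_factory=dict)  # (tool, cat) -> (thr, nacc)
    polarities: dict = field(default_factory=dict)  # tool -> polarity

    def set(self, tool: str, category: str, threshold: float,
            nacc: float, polarity: str) -> None:
        self.entries[(tool, category)] = (float(threshold), float(nacc))
        prev = self.polarities.get(tool)
        if prev is not None and prev != polarity:
            raise ValueError(f"conflicting polarity for tool {tool!r}")
        self.polarities[tool] = polarity

    def get(self, tool: str, category: str) -> float:
        return self.entries[(tool, category)][0]

    def training_accuracy(self, tool: str, category: str) -> float:
        return self.entries[(tool, category)][1]

    def polarity(self, tool: str) -> str:
        return self.polarities[tool]

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"tool": t, "category": c, "threshold": thr, "normalized_accuracy": acc}
                for (t, c), (thr, acc) in sorted(self.entries.items())
            ],
            "polarities": dict(sorted(self.polarities.items())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        tm = cls()
        tm.polarities = dict(d["polarities"])
        for e in d["entries"]:
            tm.entries[(e["tool"], e["category"])] = (
                float(e["threshold"]), float(e["normalized_accuracy"])
            )
        return tm


def predict_binary(score: float, threshold: float, polarity: str) -> str:
    """Apply the (inclusive) threshold rule; returns ``"D"`` or ``"N"``."""
    if polarity == HIGHER_IS_DELETERIOUS:
        return "D" if score >= threshold else "N"
    if polarity == LOWER_IS_DELETERIOUS:
        return "D" if score <= threshold else "N"
    raise ValueError(f"unknown polarity {polarity!r}")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated symmetrically at the edges.

    At index i with half-width h = window // 2, the effective half-width is
    min(h, i, n-1-i), so the window stays centered and never runs off the
    array; a constant input is returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    h = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = v[i - k: i + k + 1].mean()
    return out


@dataclass
class CalibrationCurve:
    """Binned, smoothed raw-score -> fraction-deleterious transform.

    ``bin_centers`` are the mean raw score per bin (ascending);
    ``smoothed_frac_deleterious`` are the per-bin deleterious fractions
    after moving-average smoothing.  ``bin_edges`` record the score
    boundaries between bins for inspection.
    """

    tool: str
    category: str
    bin_edges: list[float]
    bin_centers: list[float]
    smoothed_frac_deleterious: list[float]
    threshold: float
    n_bins: int
    window: int

    def to_dict(self) -> dict:
        return {
            "bin_edges": list(map(float, self.bin_edges)),
            "bin_centers": list(map(float, self.bin_centers)),
            "smoothed_frac_deleterious": list(map(float, self.smoothed_frac_deleterious)),
            "threshold": float(self.threshold),
            "n_bins": int(self.n_bins),
            "window": int(self.window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            tool=d.get("tool", ""),
            category=d.get("category", ""),
            bin_edges=list(d["bin_edges"]),
            bin_centers=list(d["bin_centers"]),
            smoothed_frac_deleterious=list(d["smoothed_frac_deleterious"]),
            threshold=float(d["threshold"]),
            n_bins=int(d["n_bins"]),
            window=int(d["window"]),
        )


def fit_confidence_curve(scores: Sequence[float], labels: Sequence,
                         threshold: float, n_bins: int = DEFAULT_N_BINS,
                         window: int = DEFAULT_WINDOW, *,
                         tool: str = "", category: str = ""
                         ) -> CalibrationCurve:
    """Fit the binned observed-accuracy calibration curve.

    Training points are sorted by raw score and split into
    ``min(n_bins, n // 2)`` bins so each bin holds at least two points;
    remainder points go one per bin starting from the lowest-score bin.
    Per-bin deleterious fractions are then smoothed with a centered moving
    average of width ``window`` (edge-truncated).
    """
    s = np.asarray(scores, dtype=float)
    y = as_deleterious_mask(labels)
    if s.size != y.size:
        raise ValueError("scores and labels differ in length")
    if s.size < 4:
        raise ValueError("need at least 4 training points to fit a curve")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to fit a curve")
    order = np.argsort(s, kind="stable")
    s = s[order]
    y = y[order]
    n = s.size
    n_eff = min(int(n_bins), n // 2)
    base, rem = divmod(n, n_eff)
    sizes = np.full(n_eff, base, dtype=int)
    sizes[:rem] += 1
    stops = np.cumsum(sizes)
    starts = stops - sizes

    centers = np.array([s[a:b].mean() for a, b in zip(starts, stops)])
    fracs = np.array([y[a:b].mean() for a, b in zip(starts, stops)])
    smoothed = moving_average(fracs, window)
    edges = np.concatenate(
        ([s[0]], (s[stops[:-1] - 1] + s[stops[:-1]]) / 2.0, [s[-1]])
    )
    return CalibrationCurve(
        tool=tool, category=category,
        bin_edges=edges.tolist(), bin_centers=centers.tolist(),
        smoothed_frac_deleterious=smoothed.tolist(),
        threshold=float(threshold), n_bins=int(n_eff), window=int(window),
    )


def transform_score(curve: CalibrationCurve, raw: float,
                    polarity: str = HIGHER_IS_DELETERIOUS) -> tuple[str, int]:
    """Map a raw score to ``(prediction, confidence)``.

    The prediction comes from the threshold rule.  The confidence is the
    side-specific observed accuracy: the smoothed fraction-deleterious at
    the query score (linearly interpolated between bin centers, clamped to
    the outermost bin beyond the training range) for a deleterious call,
    and its complement for a neutral call, scaled to an integer capped at
    99.
    """
    pred = predict_binary(raw, curve.threshold, polarity)
    centers = np.asarray(curve.bin_centers)
    fracs = np.asarray(curve.smoothed_frac_deleterious)
    frac = float(np.interp(raw, centers, fracs))
    acc = frac if pred == "D" else 1.0 - frac
    conf = min(99, int(round(100.0 * acc)))
    return pred, conf
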