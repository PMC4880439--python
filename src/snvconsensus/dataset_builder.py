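"""Balanced, leakage-controlled train/test dataset construction.

Deleterious variants are paired 1:1 with nearby neutral controls (greedy
nearest-neighbor on genomic distance, without replacement), after removing
any neutral variant that also appears in a disease set.  Train/test splits
are either time-based (strictly after a cutoff date -> test), or — for
exonic categories — leakage-controlled by greedy protein-identity
clustering so that variants in similar proteins never straddle the split.
"""

from __future__ import annotations

import datetime as _dt
import logging
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .core_io import Variant, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.50


@dataclass
class MatchedPair:
    """A deleterious variant with its matched neutral control."""

    deleterious: Variant
    neutral: Variant
    distance: int

    def __post_init__(self) -> None:
        if normalize_chrom(self.deleterious.chrom) != normalize_chrom(self.neutral.chrom):
            raise ValueError("matched pair must share a chromosome")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class ProteinCluster:
    """A greedy identity cluster: representative plus members."""

    representative: str
    members: list[str]
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD


def remove_overlaps(neutral_pool: Sequence[Variant],
                    disease_sets: Sequence[Iterable[Variant]]
                    ) -> list[Variant]:
    """Drop neutral variants whose allele-specific key appears in any
    disease set.  Removal counts per disease set are logged."""
    keysets = [ {v.key for v in ds} for ds in disease_sets ]
    retained: list[Variant] = []
    removed = [0] * len(keysets)
    for v in neutral_pool:
        hit = False
        for i, ks in enumerate(keysets):
            if v.key in ks:
                removed[i] += 1
                hit = True
        if not hit:
            retained.append(v)
    for i, count in enumerate(removed):
        if count:
            logger.info("removed %d neutral variants overlapping disease set %d",
                        count, i)
    return retained


def match_neutral(deleterious: Sequence[Variant],
                  neutral_pool: Sequence[Variant]) -> list[MatchedPair]:
    """Greedy nearest-neighbor matching of neutral controls, without
    replacement.

    Deleterious variants are processed in (chrom, pos) order; each takes
    the nearest unused neutral variant on the same chromosome (distance
    ties go to the lower position).  Deleterious variants with no
    same-chromosome candidate left are dropped with a warning, so the
    result is exactly 1:1 balanced.
    """
    if not neutral_pool:
        raise ValueError("neutral pool is empty")
    by_chrom: dict[str, list[tuple[int, Variant]]] = {}
    for v in neutral_pool:
        by_chrom.setdefault(normalize_chrom(v.chrom), []).append((v.pos, v))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0])

    pairs: list[MatchedPair] = []
    dropped = 0
    for d in sorted(deleterious, key=lambda v: (normalize_chrom(v.chrom), v.pos)):
        candidates = by_chrom.get(normalize_chrom(d.chrom))
        if not candidates:
            dropped += 1
            continue
        i = _bisect_pos(candidates, d.pos)
        best_idx = None
        if i < len(candidates):
            best_idx = i
        if i > 0:
            left_dist = d.pos - candidates[i - 1][0]
            if best_idx is None or left_dist <= candidates[best_idx][0] - d.pos:
                # tie -> lower position (the left candidate)
                best_idx = i - 1
        pos, n = candidates.pop(best_idx)
        pairs.append(MatchedPair(deleterious=d, neutral=n, distance=abs(d.pos - pos)))
        if not candidates:
            del by_chrom[normalize_chrom(d.chrom)]
    if dropped:
        logger.warning("dropped %d deleterious variants with no available "
                       "neutral match", dropped)
    return pairs


def _bisect_pos(candidates: list[tuple[int, Variant]], pos: int) -> int:
    lo, hi = 0, len(candidates)
    while lo < hi:
        mid = (lo + hi) // 2
        if candidates[mid][0] < pos:
            lo = mid + 1
        else:
            hi = mid
    return lo


def split_by_date(variants: Sequence[Variant], cutoff: _dt.date
                  ) -> tuple[list[Variant], list[Variant]]:
    """Time-based split: submission date strictly after *cutoff* -> test."""
    train: list[Variant] = []
    test: list[Variant] = []
    for v in variants:
        if v.date is None:
            raise ValueError(f"variant {v.key} has no submission date")
        (test if v.date > cutoff else train).append(v)
    if not test:
        logger.warning("date split produced an empty test set (all dates "
                       "on or before %s)", cutoff)
    return train, test


def split_pairs_by_date(pairs: Sequence[MatchedPair], cutoff: _dt.date
                        ) -> tuple[list[MatchedPair], list[MatchedPair]]:
    """A matched pair goes wholly to the side of its deleterious member."""
    train: list[MatchedPair] = []
    test: list[MatchedPair] = []
    for p in pairs:
        if p.deleterious.date is None:
            raise ValueError(f"variant {p.deleterious.key} has no submission date")
        (test if p.deleterious.date > cutoff else train).append(p)
    return train, test


# ---------------------------------------------------------------------------
# Protein identity and clustering

_aligner: Optional[Align.PairwiseAligner] = None


def _global_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -1.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity, CD-HIT style.

    Identical residues in the optimal global alignment (match +1,
    mismatch 0, gap open -1, gap extend -0.5), divided by the length of
    the shorter sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _global_aligner().align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def greedy_identity_clusters(sequences: Mapping[str, str],
                             threshold: float = DEFAULT_IDENTITY_THRESHOLD
                             ) -> list[ProteinCluster]:
    """Greedy incremental clustering by identity to cluster representatives.

    Sequences are processed by descending length (ties by id for
    determinism); each joins the first existing cluster whose
    representative it matches at >= *threshold* identity, else founds a
    new cluster with itself as representative.
    """
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[ProteinCluster] = []
    for sid in order:
        seq = sequences[sid]
        for cl in clusters:
            if pairwise_identity(sequences[cl.representative], seq) >= threshold:
                cl.members.append(sid)
                break
        else:
            clusters.append(ProteinCluster(representative=sid, members=[sid],
                                           identity_threshold=threshold))
    return clusters


def cluster_split_exonic(variants: Sequence[Variant],
                         protein_map: Mapping[tuple, str],
                         sequences: Mapping[str, str],
                         threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                         test_fraction: float = 0.5,
                         seed: int = 0
                         ) -> tuple[list[Variant], list[Variant]]:
    """Leakage-controlled split of exonic variants by protein clusters.

    Whole clusters are assigned to the test side by seeded shuffle until
    the test fraction (by variant count) is approximately met; no cluster
    is ever split across sides.
    """
    for v in variants:
        if v.key not in protein_map:
            raise ValueError(f"variant {v.key} has no protein mapping")
    clusters = greedy_identity_clusters(sequences, threshold)
    member_to_cluster = {m: i for i, cl in enumerate(clusters) for m in cl.members}
    variants_per_cluster: dict[int, list[Variant]] = {}
    for v in variants:
        ci = member_to_cluster[protein_map[v.key]]
        variants_per_cluster.setdefault(ci, []).append(v)

    rng = random.Random(seed)
    order = sorted(variants_per_cluster)
    rng.shuffle(order)
    target = test_fraction * len(variants)
    test: list[Variant] = []
    train: list[Variant] = []
    placed = 0
    for ci in order:
        vs = variants_per_cluster[ci]
        if placed < target:
            test.extend(vs)
            placed += len(vs)
        else:
            train.extend(vs)
    return train, test


def random_split(variants: Sequence[Variant], test_fraction: float = 0.5,
                 seed: int = 0) -> tuple[list[Variant], list[Variant]]:
    """Seeded uniform random partition, used for non-exonic categories."""
    rng = random.Random(seed)
    idx = list(range(len(variants)))
    rng.shuffle(idx)
    n_test = int(round(test_fraction * len(variants)))
    test_idx = set(idx[:n_test])
    train = [v for i, v in enumerate(variants) if i not in test_idx]
    test = [v for i, v in enumerate(variants) if i in test_idx]
    return train, test
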