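"""Hierarchical read classification, strand bias, duplex typing, saturation.

Each read receives exactly one annotation category. When a read overlaps
several features (e.g. a tRNA encoded within an mRNA intron), the category
ranked highest in the priority order wins; structural ncRNAs outrank the
mRNA moieties they are nested in. Strand bias per category is summarized as
a log-odds (Lods) ratio of sense to antisense mapped weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_io import (
    AlignedRead,
    AnnotationFeature,
    CATEGORIES,
    CoverageTrack,
    GenomicInterval,
    SizeDistribution,
    build_coverage,
    covered_length,
)

#: Default category priority, high to low. Structural ncRNAs first, then
#: transposons, then mRNA moieties; intergenic is the fallback.
DEFAULT_PRIORITY: tuple[str, ...] = CATEGORIES

DEFAULT_LODS_PSEUDOCOUNT = 1.0
DEFAULT_BALANCE_THRESHOLD = 0.2
DEFAULT_MIN_DUPLEX_WEIGHT = 5.0


class AnnotationIndex:
    """Interval-tree index over annotation features for overlap queries."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self.trees: dict[str, IntervalTree] = {}
        for f in features:
            iv = f.interval
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, f)

    def overlapping(self, interval: GenomicInterval) -> list[AnnotationFeature]:
        tree = self.trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]


@dataclass
class ClassificationSummary:
    """Per-category read counts and sense/antisense weight totals."""

    counts: dict[str, int] = field(default_factory=dict)
    sense_weight: dict[str, float] = field(default_factory=dict)
    antisense_weight: dict[str, float] = field(default_factory=dict)

    def total_reads(self) -> int:
        return sum(self.counts.values())

    def lods(self, category: str, pseudocount: float = DEFAULT_LODS_PSEUDOCOUNT) -> float:
        return strand_lods(
            self.sense_weight.get(category, 0.0),
            self.antisense_weight.get(category, 0.0),
            pseudocount,
        )


def classify_read(
    read: AlignedRead,
    index: AnnotationIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple[str, str]:
    """Assign one category and an orientation to a read.

    Among overlapped features the highest-priority category wins; ties
    within a category resolve to the largest overlap, then the leftmost
    feature. Orientation is ``sense`` iff the read strand equals the feature
    strand; a read is sense/antisense to a feature only if the feature's
    strand is declared. No overlap yields ``("intergenic", "unstranded")``.
    """
    hits = index.overlapping(read.interval)
    if not hits:
        return "intergenic", "unstranded"
    rank = {cat: i for i, cat in enumerate(priority)}
    best = min(
        hits,
        key=lambda f: (
            rank.get(f.category, len(priority)),
            -read.interval.overlap(f.interval),
            f.interval.start,
            f.feature_id,
        ),
    )
    if best.interval.strand == "." or read.interval.strand == ".":
        orientation = "unstranded"
    elif read.interval.strand == best.interval.strand:
        orientation = "sense"
    else:
        orientation = "antisense"
    return best.category, orientation


def summarize_classes(
    reads: Iterable[AlignedRead],
    index: AnnotationIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> ClassificationSummary:
    """Classify every read and accumulate counts and stranded weights.

    Count conservation holds: the summary's counts sum to the number of
    reads. Unstranded orientations contribute to neither sense nor
    antisense weight.
    """
    summary = ClassificationSummary()
    for read in reads:
        category, orientation = classify_read(read, index, priority)
        summary.counts[category] = summary.counts.get(category, 0) + 1
        if orientation == "sense":
            summary.sense_weight[category] = (
                summary.sense_weight.get(category, 0.0) + read.weight
            )
        elif orientation == "antisense":
            summary.antisense_weight[category] = (
                summary.antisense_weight.get(category, 0.0) + read.weight
            )
    return summary


def strand_lods(
    sense: float, antisense: float, pseudocount: float = DEFAULT_LODS_PSEUDOCOUNT
) -> float:
    """log10 odds of sense to antisense weight, with a pseudocount.

    Antisymmetric: ``strand_lods(S, A) == -strand_lods(A, S)``; zero when
    the two weights are equal.
    """
    if sense < 0 or antisense < 0:
        raise ValueError("weights must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log10((sense + pseudocount) / (antisense + pseudocount))


def duplex_type(
    plus_weight: float,
    minus_weight: float,
    balance_threshold: float = DEFAULT_BALANCE_THRESHOLD,
    min_weight: float = DEFAULT_MIN_DUPLEX_WEIGHT,
) -> str:
    """Type a duplex locus as intra-molecular fold-back or inter-molecular.

    ``inter`` (heteroduplex of complementary transcripts) requires both
    strands to carry at least ``min_weight`` and the minority strand to hold
    at least ``balance_threshold`` of the total; otherwise the signal is a
    one-strand fold-back, ``intra``.
    """
    if plus_weight < 0 or minus_weight < 0:
        raise ValueError("weights must be non-negative")
    total = plus_weight + minus_weight
    if total == 0:
        raise ValueError("no duplex evidence: both strand weights are zero")
    minority = min(plus_weight, minus_weight)
    if minority >= min_weight and minority / total >= balance_threshold:
        return "inter"
    return "intra"


def size_distribution(
    reads: Iterable[AlignedRead], min_len: int = 19, max_len: int = 26
) -> SizeDistribution:
    """Total read weight per length class (outside range pooled as 'other')."""
    dist = SizeDistribution(min_len=min_len, max_len=max_len)
    for read in reads:
        dist.add(read.length, read.weight)
    return dist


def subsample_saturation(
    reads: Sequence[AlignedRead],
    chrom_sizes: Mapping[str, int],
    index: AnnotationIndex,
    fractions: Sequence[float],
    n_reps: int = 3,
    seed: int = 0,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, dict[float, float]]:
    """Coverage-saturation curves by library subsampling.

    For each fraction, each read is kept independently with that
    probability (averaged over ``n_reps`` replicates) and the covered
    length per category — plus an ``overall`` track — is divided by the
    covered length of the full library, so every curve ends at exactly 1.0.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    read_cat = [classify_read(r, index, priority)[0] for r in reads]
    categories = sorted(set(read_cat))

    def category_covered(kept: Sequence[AlignedRead], kept_cat: Sequence[str]):
        out: dict[str, int] = {}
        track = build_coverage(kept, chrom_sizes)
        out["overall"] = covered_length(track)
        for cat in categories:
            sub = [r for r, c in zip(kept, kept_cat) if c == cat]
            out[cat] = covered_length(build_coverage(sub, chrom_sizes)) if sub else 0
        return out

    full = category_covered(reads, read_cat)
    curves: dict[str, dict[float, float]] = {cat: {} for cat in full}
    for frac in fractions:
        acc = {cat: 0.0 for cat in full}
        for _ in range(n_reps):
            if frac == 1.0:
                keep = np.ones(len(reads), dtype=bool)
            else:
                keep = rng.random(len(reads)) < frac
            kept = [r for r, k in zip(reads, keep) if k]
            kept_cat = [c for c, k in zip(read_cat, keep) if k]
            cov = category_covered(kept, kept_cat)
            for cat in full:
                acc[cat] += cov[cat]
        for cat in full:
            denom = full[cat]
            curves[cat][frac] = (acc[cat] / n_reps / denom) if denom else 0.0
    return curves
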