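"""Geometric-model hotspot calling on read-covered segments.

Contiguous read-covered segments of the genome are treated as observations
of double-stranded RNA molecules. Segment lengths are modelled per
chromosome by a geometric distribution fit by the method of moments
(p = 1 / mean length), and a segment is an unusually long "hotspot" when
its geometric tail probability P(X >= L) = (1-p)^(L-1) survives
Benjamini-Hochberg correction across all tested segments genome-wide.
The identical machinery applies to small-RNA libraries to call smRNA
hotspots.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control

from .classify import (
    AnnotationIndex,
    DEFAULT_PRIORITY,
    strand_lods,
)
from .core_io import AlignedRead, CoverageTrack, GenomicInterval

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_READS = 2


@dataclass
class CoveredSegment:
    """A maximal run of bases with combined-strand depth above threshold."""

    interval: GenomicInterval
    read_count: int = 0
    plus_weight: float = 0.0
    minus_weight: float = 0.0

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def total_weight(self) -> float:
        return self.plus_weight + self.minus_weight


@dataclass(frozen=True)
class GeometricModel:
    """Per-chromosome geometric segment-length model, support {1, 2, ...}."""

    chrom: str
    mean_length: float
    p_hat: float
    n_segments: int

    def __post_init__(self):
        if not (0 < self.p_hat <= 1):
            raise ValueError("p_hat must lie in (0, 1]")


@dataclass
class Hotspot:
    """A significantly long covered segment."""

    segment: CoveredSegment
    p_value: float
    q_value: float
    hotspot_id: str = ""
    category: str = "intergenic"
    lods: float = 0.0

    @property
    def interval(self) -> GenomicInterval:
        return self.segment.interval


def merge_segments(
    track: CoverageTrack,
    reads: Sequence[AlignedRead] | None = None,
    min_depth: float = 0.0,
) -> list[CoveredSegment]:
    """Extract maximal covered segments from a coverage track.

    A segment is a maximal run of bases whose combined-strand depth exceeds
    ``min_depth`` (default: any positive depth). When the contributing reads
    are supplied, each segment records its distinct-read count and
    per-strand weight sums (a read is attributed to the segment holding its
    start).
    """
    segments: list[CoveredSegment] = []
    for chrom in track.chrom_sizes:
        depth = track.combined(chrom)
        mask = depth > min_depth if min_depth > 0 else depth > 0
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        for s, e in zip(starts, ends):
            segments.append(CoveredSegment(GenomicInterval(chrom, int(s), int(e), ".")))
    segments.sort(key=lambda seg: (seg.interval.chrom, seg.interval.start))
    if reads is not None:
        _attribute_reads(segments, reads)
    return segments


def _attribute_reads(segments: list[CoveredSegment], reads: Iterable[AlignedRead]) -> None:
    by_chrom: dict[str, list[CoveredSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    starts = {c: [s.interval.start for s in segs] for c, segs in by_chrom.items()}
    for read in reads:
        iv = read.interval
        segs = by_chrom.get(iv.chrom)
        if not segs:
            continue
        idx = bisect_right(starts[iv.chrom], iv.start) - 1
        if idx < 0 or iv.start >= segs[idx].interval.end:
            continue
        seg = segs[idx]
        seg.read_count += 1
        if iv.strand == "-":
            seg.minus_weight += read.weight
        else:
            seg.plus_weight += read.weight


def fit_geometric(segments: Sequence[CoveredSegment], chrom: str | None = None) -> GeometricModel:
    """Method-of-moments geometric fit to segment lengths on one chromosome.

    With mean observed length L-bar, the success parameter is p = 1/L-bar.
    Requires at least two segments; with fewer, fit a pooled model across
    chromosomes instead (see :func:`fit_models`).
    """
    if chrom is not None:
        segments = [s for s in segments if s.interval.chrom == chrom]
    if len(segments) < 2:
        raise ValueError(
            "need >= 2 segments to fit a per-chromosome geometric model; "
            "use a pooled fallback model across chromosomes"
        )
    lengths = np.array([s.length for s in segments], dtype=float)
    mean_len = float(lengths.mean())
    return GeometricModel(
        chrom=chrom if chrom is not None else "*pooled*",
        mean_length=mean_len,
        p_hat=1.0 / mean_len,
        n_segments=len(segments),
    )


def fit_models(segments: Sequence[CoveredSegment]) -> dict[str, GeometricModel]:
    """Fit one geometric model per chromosome, pooling when a chromosome is sparse."""
    chroms = sorted({s.interval.chrom for s in segments})
    models: dict[str, GeometricModel] = {}
    sparse: list[str] = []
    for chrom in chroms:
        try:
            models[chrom] = fit_geometric(segments, chrom)
        except ValueError:
            sparse.append(chrom)
    if sparse:
        pooled = fit_geometric(segments)
        for chrom in sparse:
            models[chrom] = replace(pooled, chrom=chrom)
    return models


def geometric_tail(length: int, p_hat: float) -> float:
    """Upper-tail probability P(X >= L) = (1-p)^(L-1) for geometric X on {1,2,...}."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < p_hat <= 1):
        raise ValueError("p_hat must lie in (0, 1]")
    return (1.0 - p_hat) ** (length - 1)


def call_hotspots(
    segments: Sequence[CoveredSegment],
    models: Mapping[str, GeometricModel] | GeometricModel,
    alpha: float = DEFAULT_ALPHA,
    min_reads: int = DEFAULT_MIN_READS,
    index: AnnotationIndex | None = None,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[Hotspot]:
    """Call hotspots by geometric tail test with genome-wide BH correction.

    Segments with fewer than ``min_reads`` distinct supporting reads are
    excluded before testing (when read counts are available). The remaining
    segments receive a tail p-value from their chromosome's model, BH
    q-values across all tested segments, and a hotspot is called at
    q <= alpha. Ids are ``{chrom}_h{k}`` in coordinate order per chromosome;
    each hotspot carries the majority-overlap annotation category and the
    sense-free strand log-odds of its plus/minus weights.
    """
    testable = [
        s for s in segments if s.read_count == 0 or s.read_count >= min_reads
    ]
    if not testable:
        return []
    if isinstance(models, GeometricModel):
        models = {c: models for c in {s.interval.chrom for s in testable}}
    pvals = np.array(
        [geometric_tail(s.length, models[s.interval.chrom].p_hat) for s in testable]
    )
    qvals = false_discovery_control(pvals, method="bh")
    called = [
        (seg, p, q)
        for seg, p, q in zip(testable, pvals, qvals)
        if q <= alpha
    ]
    called.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start))
    hotspots: list[Hotspot] = []
    counter: dict[str, int] = {}
    for seg, p, q in called:
        chrom = seg.interval.chrom
        counter[chrom] = counter.get(chrom, 0) + 1
        category = "intergenic"
        if index is not None:
            category = _majority_category(seg.interval, index, priority)
        hotspots.append(
            Hotspot(
                segment=seg,
                p_value=float(p),
                q_value=float(q),
                hotspot_id=f"{chrom}_h{counter[chrom]}",
                category=category,
                lods=strand_lods(seg.plus_weight, seg.minus_weight),
            )
        )
    return hotspots


def _majority_category(
    interval: GenomicInterval, index: AnnotationIndex, priority: Sequence[str]
) -> str:
    """Category with the largest base overlap; priority order breaks ties."""
    hits = index.overlapping(interval)
    if not hits:
        return "intergenic"
    overlap: dict[str, int] = {}
    for f in hits:
        overlap[f.category] = overlap.get(f.category, 0) + interval.overlap(f.interval)
    rank = {cat: i for i, cat in enumerate(priority)}
    return max(overlap, key=lambda c: (overlap[c], -rank.get(c, len(priority))))


def hotspot_smrna_overlap(
    hotspots: Sequence[Hotspot], smrna_track: CoverageTrack
) -> dict[str, float]:
    """Percent of hotspot nucleotides with small-RNA coverage, per category.

    Categories without hotspots are omitted from the result.
    """
    covered: dict[str, int] = {}
    total: dict[str, int] = {}
    for h in hotspots:
        iv = h.interval
        depth = smrna_track.combined(iv.chrom)[iv.start : iv.end]
        covered[h.category] = covered.get(h.category, 0) + int((depth > 0).sum())
        total[h.category] = total.get(h.category, 0) + len(iv)
    return {cat: 100.0 * covered[cat] / total[cat] for cat in total}


@dataclass
class NovelUnit:
    """An unannotated (intergenic) hotspot: a candidate novel transcript."""

    hotspot: Hotspot
    overlaps_smrna_hotspot: bool
    size_classes: dict = field(default_factory=dict)


def discover_novel(
    hotspots: Sequence[Hotspot],
    index: AnnotationIndex,
    smrna_hotspots: Sequence[Hotspot],
    smrna_reads: Sequence[AlignedRead] | None = None,
) -> list[NovelUnit]:
    """Nominate novel transcription units from unannotated hotspots.

    A novel unit is a hotspot with zero overlap to any annotated feature.
    Each unit is flagged when it overlaps an smRNA hotspot by at least one
    base, and (when small-RNA reads are supplied) carries the weight of
    overlapping small RNAs per 19-26 nt size class.
    """
    sm_by_chrom: dict[str, list[GenomicInterval]] = {}
    for h in smrna_hotspots:
        sm_by_chrom.setdefault(h.interval.chrom, []).append(h.interval)
    units: list[NovelUnit] = []
    for h in hotspots:
        if index.overlapping(h.interval):
            continue
        overlaps = any(
            h.interval.overlap(iv) > 0 for iv in sm_by_chrom.get(h.interval.chrom, [])
        )
        sizes: dict = {}
        if smrna_reads is not None:
            from .classify import size_distribution

            in_unit = [
                r for r in smrna_reads if r.interval.overlap(h.interval) > 0
            ]
            sizes = size_distribution(in_unit).weights
        units.append(NovelUnit(hotspot=h, overlaps_smrna_hotspot=overlaps, size_classes=sizes))
    return units


def write_hotspots_bed(hotspots: Sequence[Hotspot], path) -> None:
    """Write hotspots as BED6+ (id, score=length, extra: p, q, category, lods)."""
    with open(path, "w") as fh:
        for h in hotspots:
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.hotspot_id}\t{h.segment.length}\t.\t"
                f"{h.p_value:.6g}\t{h.q_value:.6g}\t{h.category}\t{h.lods:.4f}\n"
            )
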