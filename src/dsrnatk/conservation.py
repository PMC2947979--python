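"""Conservation of hotspots versus flanking sequence within genomic moieties.

Per-base conservation scores (consScore, from a multi-species whole-genome
alignment) are consumed as a bedGraph; the alignment pipeline that produces
them is upstream of this toolkit. Within each structural moiety of mRNAs
(coding exons, both UTRs, introns) as well as intergenic space and
transposons, hotspot bases are compared against all remaining moiety bases
("flanking regions"): per-region mean scores on the two sides enter a
two-sided Wilcoxon rank-sum test. Testing region means rather than raw
per-base scores avoids pseudo-replication from the strong spatial
autocorrelation of conservation tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .core_io import AnnotationFeature, GenomicInterval, RecordError
from .hotspots import Hotspot

logger = logging.getLogger("dsrnatk")

#: Moieties compared in the hotspot-vs-flanking analysis.
MOIETIES = ("exon_CDS", "UTR5", "UTR3", "intron", "intergenic", "transposable_element")

DEFAULT_MIN_SCORED_BASES = 10


class ConservationTrack:
    """Per-chromosome per-base conservation scores; missing bases are NaN."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.scores = {
            c: np.full(n, np.nan, dtype=np.float64) for c, n in self.chrom_sizes.items()
        }

    def set_region(self, chrom: str, start: int, end: int, value: float) -> None:
        self.scores[chrom][start:end] = value

    def values(self, region: GenomicInterval) -> np.ndarray:
        return self.scores[region.chrom][region.start : region.end]


def read_cons_bedgraph(path, chrom_sizes: Mapping[str, int]) -> ConservationTrack:
    """Load a conservation bedGraph into a dense per-base track."""
    track = ConservationTrack(chrom_sizes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise RecordError(path, lineno, "expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = parts
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                raise RecordError(path, lineno, "malformed bedGraph record") from None
            if chrom not in chrom_sizes:
                raise RecordError(path, lineno, f"unknown chromosome {chrom!r}")
            if not np.isfinite(value):
                raise RecordError(path, lineno, "non-finite score")
            track.set_region(chrom, start, end, value)
    return track


def write_cons_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.scores.items():
            present = np.isfinite(arr)
            if not present.any():
                continue
            # emit runs of identical finite values
            start = None
            for i in range(arr.size + 1):
                if i < arr.size and present[i] and (
                    start is None or arr[i] == arr[start]
                ):
                    if start is None:
                        start = i
                    continue
                if start is not None:
                    fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:.6g}\n")
                start = i if i < arr.size and present[i] else None


def mean_cons(region: GenomicInterval, track: ConservationTrack) -> tuple[float, int]:
    """Mean conservation score over scored bases of a region.

    Returns ``(mean, n_missing)``; a region with no scored bases yields
    ``(nan, len(region))`` and is dropped by callers.
    """
    vals = track.values(region)
    present = np.isfinite(vals)
    n_missing = int((~present).sum())
    if not present.any():
        return float("nan"), n_missing
    return float(vals[present].mean()), n_missing


def _subtract_intervals(
    feature: GenomicInterval, cuts: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Feature bases minus cut bases, as maximal intervals."""
    mask = np.ones(len(feature), dtype=bool)
    for cut in cuts:
        if cut.chrom != feature.chrom:
            continue
        s = max(cut.start, feature.start) - feature.start
        e = min(cut.end, feature.end) - feature.start
        if e > s:
            mask[s:e] = False
    out: list[GenomicInterval] = []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[0::2], edges[1::2]):
        out.append(
            GenomicInterval(feature.chrom, feature.start + int(s), feature.start + int(e), ".")
        )
    return out


def flanking_complement(
    hotspots: Sequence[Hotspot | GenomicInterval],
    moiety_features: Sequence[AnnotationFeature | GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split moiety bases into hotspot portions and flanking complement.

    For each moiety feature, the bases overlapped by any hotspot are emitted
    as hotspot-within-moiety intervals and the remaining bases as flanking
    intervals; the two sets are disjoint and together cover the moiety.
    """
    hs_ivs = [h.interval if isinstance(h, Hotspot) else h for h in hotspots]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in hs_ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hot_regions: list[GenomicInterval] = []
    flank_regions: list[GenomicInterval] = []
    for f in moiety_features:
        iv = f.interval if isinstance(f, AnnotationFeature) else f
        cuts = [h for h in by_chrom.get(iv.chrom, []) if iv.overlap(h) > 0]
        flank_regions.extend(_subtract_intervals(iv, cuts))
        # hotspot portion = feature minus flanking
        flanks_here = _subtract_intervals(iv, cuts)
        hot_regions.extend(_subtract_intervals(iv, flanks_here))
    return hot_regions, flank_regions


@dataclass
class CategoryComparison:
    """Hotspot-vs-flanking conservation comparison for one moiety."""

    moiety: str
    hotspot_means: list[float]
    flanking_means: list[float]
    statistic: float
    p_value: float
    direction: str  # "hotspot>flanking", "hotspot<flanking" or "none"


def compare_category(
    hotspot_means: Sequence[float],
    flanking_means: Sequence[float],
    moiety: str = "",
) -> CategoryComparison:
    """Two-sided Wilcoxon rank-sum on per-region mean conservation scores.

    Direction follows the sign of (median hotspot - median flanking);
    swapping the two lists flips the direction and preserves the p-value.
    At least two regions per side are required.
    """
    hot = [m for m in hotspot_means if np.isfinite(m)]
    fla = [m for m in flanking_means if np.isfinite(m)]
    if len(hot) < 2 or len(fla) < 2:
        raise ValueError("need >= 2 scored regions on each side; comparison skipped")
    if hot == fla:
        stat, p = float(len(hot) * len(fla) / 2), 1.0
    else:
        stat, p = mannwhitneyu(hot, fla, alternative="two-sided")
    diff = float(np.median(hot) - np.median(fla))
    if diff > 0:
        direction = "hotspot>flanking"
    elif diff < 0:
        direction = "hotspot<flanking"
    else:
        direction = "none"
    return CategoryComparison(
        moiety=moiety,
        hotspot_means=list(hot),
        flanking_means=list(fla),
        statistic=float(stat),
        p_value=float(p),
        direction=direction,
    )


def compare_all(
    hotspots: Sequence[Hotspot],
    features: Sequence[AnnotationFeature],
    track: ConservationTrack,
    min_scored: int = DEFAULT_MIN_SCORED_BASES,
) -> dict[str, CategoryComparison]:
    """Run the hotspot-vs-flanking comparison in every moiety with data.

    Regions with fewer than ``min_scored`` scored bases are excluded;
    moieties with fewer than two usable regions on either side are skipped
    with a log note.
    """
    comparisons: dict[str, CategoryComparison] = {}
    for moiety in MOIETIES:
        moiety_feats = [f for f in features if f.category == moiety]
        if not moiety_feats:
            continue
        hot_regions, flank_regions = flanking_complement(hotspots, moiety_feats)

        def region_means(regions: Iterable[GenomicInterval]) -> list[float]:
            means = []
            for r in regions:
                scored = len(r) - mean_cons(r, track)[1]
                if scored < min_scored:
                    continue
                m, _ = mean_cons(r, track)
                if np.isfinite(m):
                    means.append(m)
            return means

        try:
            comparisons[moiety] = compare_category(
                region_means(hot_regions), region_means(flank_regions), moiety
            )
        except ValueError:
            logger.info("moiety %s skipped: fewer than 2 usable regions per side", moiety)
    return comparisons
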