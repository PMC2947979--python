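"""Core data model, format I/O, and read preprocessing for dsRNA-seq analysis.

Internal coordinates are 0-based half-open everywhere (BED convention);
GFF3 input is converted on read. Strands are ``+``, ``-`` or ``.``
(unstranded). Multi-mapped reads are fractionally weighted: an aligned
placement of a non-redundant (NR) sequence with ``copies`` clones and
``n_hits`` genomic placements carries weight ``copies / n_hits``, so the
total weight over all placements of one NR sequence equals its clone
abundance and library mass is conserved.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger("dsrnatk")

#: Closed annotation category vocabulary, from most to least structural.
#: ``intergenic`` is never stored as a feature; it is the complement.
CATEGORIES = (
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "miRNA",
    "transposable_element",
    "exon_CDS",
    "UTR5",
    "UTR3",
    "intron",
    "other_ncRNA",
    "intergenic",
)

STRANDS = ("+", "-", ".")

#: Reads shorter than this after adapter trimming are discarded (unmappable).
DEFAULT_MIN_READ_LENGTH = 15
#: Minimum exact overlap between the read 3' end and the adapter prefix.
DEFAULT_MIN_ADAPTER_OVERLAP = 5


class RecordError(ValueError):
    """A malformed record in a line-oriented file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One genomic placement of a non-redundant read sequence.

    ``copies`` is the clone abundance of the NR sequence, ``n_hits`` the
    number of genomic placements; the placement weight is ``copies/n_hits``.
    """

    interval: GenomicInterval
    copies: int = 1
    n_hits: int = 1
    name: str = "nr"

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")

    @property
    def weight(self) -> float:
        return self.copies / self.n_hits

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True, slots=True)
class AnnotationFeature:
    """An annotated genomic feature with a category from ``CATEGORIES``."""

    interval: GenomicInterval
    category: str
    feature_id: str
    parent_id: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES or self.category == "intergenic":
            raise ValueError(f"invalid feature category {self.category!r}")


class CoverageTrack:
    """Per-chromosome, per-strand arrays of weighted read depth.

    Depth at a base is the sum of weights of reads covering it. Unstranded
    reads contribute to the plus-strand array.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self.plus = {c: np.zeros(n, dtype=np.float64) for c, n in self.chrom_sizes.items()}
        self.minus = {c: np.zeros(n, dtype=np.float64) for c, n in self.chrom_sizes.items()}

    def add_read(self, read: AlignedRead) -> None:
        iv = read.interval
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"read {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end "
                f"({self.chrom_sizes[iv.chrom]})"
            )
        arr = self.minus[iv.chrom] if iv.strand == "-" else self.plus[iv.chrom]
        arr[iv.start : iv.end] += read.weight

    def depth(self, chrom: str, strand: str) -> np.ndarray:
        return self.minus[chrom] if strand == "-" else self.plus[chrom]

    def combined(self, chrom: str) -> np.ndarray:
        return self.plus[chrom] + self.minus[chrom]

    def total_mass(self) -> float:
        """Sum of depth over all bases and both strands (= sum weight x length)."""
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )


@dataclass
class SizeDistribution:
    """Total read weight per read length, with out-of-range lengths as 'other'."""

    min_len: int = 19
    max_len: int = 26
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.weights:
            self.weights = {L: 0.0 for L in range(self.min_len, self.max_len + 1)}
            self.weights["other"] = 0.0

    def add(self, length: int, weight: float) -> None:
        key = length if self.min_len <= length <= self.max_len else "other"
        self.weights[key] += weight

    def total(self) -> float:
        return sum(self.weights.values())


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def collapse_reads(sequences: Iterable[str]) -> dict[str, int]:
    """Collapse raw reads to non-redundant (NR) sequences with clone counts.

    Returns a mapping NR sequence -> copies; the sum of copies equals the
    number of input reads, so the average clone abundance is
    ``len(input) / len(result)``.
    """
    return dict(Counter(sequences))


def trim_adapter(
    seq: str, adapter: str, min_overlap: int = DEFAULT_MIN_ADAPTER_OVERLAP
) -> tuple[str, bool]:
    """Trim a 3' adapter from a read by exact prefix match at the 3' end.

    Scans for the leftmost position where a prefix of ``adapter`` (of length
    at least ``min_overlap``) matches the read exactly through the read's 3'
    end, and truncates the read at that junction. Reads without a
    recognizable adapter are returned unchanged (and retained downstream).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        tail = seq[i:]
        if len(tail) <= len(adapter) and adapter.startswith(tail):
            return seq[:i], True
    return seq, False


def preprocess_reads(
    sequences: Iterable[str],
    adapter: str | None = None,
    min_overlap: int = DEFAULT_MIN_ADAPTER_OVERLAP,
    min_length: int = DEFAULT_MIN_READ_LENGTH,
) -> dict[str, int]:
    """Collapse to NR sequences, trim adapters, and drop short products.

    Trimming is applied to NR sequences (clone counts are preserved through
    trimming and re-merged if two NR sequences trim to the same product);
    products shorter than ``min_length`` are discarded.
    """
    nr = collapse_reads(sequences)
    if adapter is None:
        return {s: c for s, c in nr.items() if len(s) >= min_length}
    out: Counter = Counter()
    for seq, copies in nr.items():
        trimmed, _found = trim_adapter(seq, adapter, min_overlap)
        if len(trimmed) >= min_length:
            out[trimmed] += copies
    return dict(out)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise RecordError(path, lineno, "expected two columns")
            try:
                size = int(parts[1])
            except ValueError:
                raise RecordError(path, lineno, f"bad size {parts[1]!r}") from None
            if size < 1:
                raise RecordError(path, lineno, "size must be >= 1")
            sizes[parts[0]] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path, chrom_sizes: Mapping[str, int] | None = None) -> list[AlignedRead]:
    """Read aligned reads from BED6.

    The score column carries the NR clone count (``copies``); the name column
    is ``NRid/n_hits``. Malformed records raise :class:`RecordError` with the
    offending line number.
    """
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise RecordError(path, lineno, f"expected 6 BED columns, got {len(parts)}")
            chrom, start_s, end_s, name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RecordError(path, lineno, "non-integer coordinates") from None
            if start >= end or start < 0:
                raise RecordError(path, lineno, f"invalid interval [{start},{end})")
            if strand not in STRANDS:
                raise RecordError(path, lineno, f"malformed strand {strand!r}")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise RecordError(path, lineno, f"unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise RecordError(path, lineno, "interval beyond chromosome end")
            nr_id, _, hits_s = name.partition("/")
            try:
                n_hits = int(hits_s) if hits_s else 1
                copies = int(score_s)
            except ValueError:
                raise RecordError(path, lineno, "non-integer copies/n_hits") from None
            try:
                reads.append(
                    AlignedRead(
                        GenomicInterval(chrom, start, end, strand),
                        copies=copies,
                        n_hits=n_hits,
                        name=nr_id,
                    )
                )
            except ValueError as exc:
                raise RecordError(path, lineno, str(exc)) from None
    return reads


def write_bed(reads: Iterable[AlignedRead], path) -> None:
    """Write aligned reads as BED6 (round-trips losslessly with read_bed)."""
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}/{r.n_hits}\t"
                f"{r.copies}\t{iv.strand}\n"
            )


#: Default mapping of common GFF3 feature types onto the category vocabulary.
DEFAULT_CATEGORY_MAP = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "miRNA": "miRNA",
    "transposable_element": "transposable_element",
    "transposable_element_gene": "transposable_element",
    "transposon_fragment": "transposable_element",
    "CDS": "exon_CDS",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "intron": "intron",
    "ncRNA": "other_ncRNA",
}


def _parse_gff_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, eq, value = item.partition("=")
        if not eq:
            raise RecordError(path, lineno, f"malformed attribute {item!r}")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(
    path, category_map: Mapping[str, str] | None = None
) -> list[AnnotationFeature]:
    """Read annotation features from GFF3, converting to 0-based half-open.

    ``category_map`` maps GFF3 type strings onto the closed category
    vocabulary; unmapped types are routed to ``other_ncRNA`` with a warning.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    features: list[AnnotationFeature] = []
    unmapped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise RecordError(path, lineno, f"expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise RecordError(path, lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise RecordError(path, lineno, f"end < start ({end1} < {start1})")
            if strand not in ("+", "-", ".", "?"):
                raise RecordError(path, lineno, f"malformed strand {strand!r}")
            attrs = _parse_gff_attributes(attr_s, path, lineno)
            category = cmap.get(ftype)
            if category is None:
                unmapped.add(ftype)
                category = "other_ncRNA"
            features.append(
                AnnotationFeature(
                    GenomicInterval(chrom, start1 - 1, end1, "." if strand == "?" else strand),
                    category=category,
                    feature_id=attrs.get("ID", f"feature_{lineno}"),
                    parent_id=attrs.get("Parent"),
                )
            )
    for ftype in sorted(unmapped):
        logger.warning("GFF3 type %r not in category map; routed to other_ncRNA", ftype)
    return features


def write_gff3(features: Iterable[AnnotationFeature], path) -> None:
    """Write features as GFF3 (1-based inclusive), inverse of :func:`read_gff3`."""
    inverse = {}
    for gff_type, cat in DEFAULT_CATEGORY_MAP.items():
        inverse.setdefault(cat, gff_type)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = f"ID={f.feature_id}"
            if f.parent_id:
                attrs += f";Parent={f.parent_id}"
            gff_type = inverse.get(f.category, f.category)
            fh.write(
                f"{iv.chrom}\tdsrnatk\t{gff_type}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(track: CoverageTrack, path, strand: str | None = None) -> None:
    """Export a coverage track as bedGraph (combined strands by default)."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            arr = track.combined(chrom) if strand is None else track.depth(chrom, strand)
            runs = _runs_of_constant(arr)
            for start, end, value in runs:
                if value != 0:
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def _runs_of_constant(arr: np.ndarray) -> Iterator[tuple[int, int, float]]:
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate([[0], change, [arr.size]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), float(arr[s])


# ---------------------------------------------------------------------------
# Coverage construction
# ---------------------------------------------------------------------------

def build_coverage(
    reads: Iterable[AlignedRead], chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    """Build per-strand weighted depth arrays from aligned reads.

    Depth at base ``b`` on strand ``s`` is the sum of weights of reads on
    ``s`` covering ``b``; total mass equals the sum of weight x length over
    reads. Reads beyond declared chromosome bounds raise ``ValueError``.
    """
    track = CoverageTrack(chrom_sizes)
    for read in reads:
        track.add_read(read)
    return track


def covered_length(track: CoverageTrack, region: GenomicInterval | None = None) -> int:
    """Number of bases with combined-strand depth > 0 (optionally in a region)."""
    if region is None:
        return int(sum((track.combined(c) > 0).sum() for c in track.chrom_sizes))
    if region.chrom not in track.chrom_sizes:
        raise ValueError(f"unknown chromosome {region.chrom!r}")
    if region.end > track.chrom_sizes[region.chrom]:
        raise ValueError("region beyond chromosome end")
    return int((track.combined(region.chrom)[region.start : region.end] > 0).sum())
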