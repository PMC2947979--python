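"""Synthetic dsRNA-seq / smRNA-seq datasets with planted ground truth.

The generator emulates the structure of a strand-specific duplex-enriched
sequencing experiment on a small genome: contiguous read-covered segments
whose lengths follow a geometric distribution (the background population of
double-stranded molecules), planted over-long fully covered hotspots,
paired wild-type/mutant libraries with planted fold-change bins in either
assay, phased small-RNA loci emitting 21-nt reads on one register, and a
per-base conservation track elevated inside hotspots. Every planted
element is recorded in a truth manifest, and a single integer seed fixes
all outputs bit-for-bit (independent substreams are derived per component,
so enabling one component never perturbs another).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .conservation import ConservationTrack, write_cons_bedgraph
from .core_io import (
    AlignedRead,
    AnnotationFeature,
    GenomicInterval,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gff3,
)

#: Default feature layout: (count, length) per category, loosely mirroring
#: the relative footprint of annotation classes on a plant chromosome arm.
DEFAULT_FEATURE_LAYOUT = {
    "rRNA": (2, 300),
    "tRNA": (4, 80),
    "snoRNA": (2, 100),
    "snRNA": (2, 150),
    "miRNA": (3, 120),
    "transposable_element": (5, 400),
    "exon_CDS": (10, 300),
    "UTR5": (10, 100),
    "UTR3": (10, 150),
    "intron": (10, 200),
    "other_ncRNA": (2, 200),
}

#: Small-RNA length distribution over 19-26 nt, peaked at the 21 and 24 nt
#: classes that dominate plant small-RNA libraries.
DEFAULT_SMRNA_LENGTH_WEIGHTS = {
    19: 0.03, 20: 0.07, 21: 0.30, 22: 0.10, 23: 0.07, 24: 0.35, 25: 0.05, 26: 0.03,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 120_000, "chr2": 80_000})
    feature_layout: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_LAYOUT))
    # background covered segments (dsRNA molecules)
    n_background_segments: int = 800
    mean_segment_length: float = 40.0
    reads_per_segment: int = 3
    max_read_length: int = 36
    inter_fraction: float = 0.15  # fraction of segments with reads on both strands
    # planted hotspots
    n_hotspots: int = 10
    hotspot_length: int = 400
    # differential 1 kb bins
    bin_width: int = 1000
    mean_bin_weight: float = 50.0
    n_diff_bins: int = 5
    diff_fold: float = 4.0
    diff_assay: str = "both"  # "dsRNA", "smRNA" or "both"
    diff_read_length: int = 30
    bin_patch_span: int = 60  # expressed patch per bin holding its reads
    smrna_length_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SMRNA_LENGTH_WEIGHTS)
    )
    # planted phased loci (placed inside planted differential bins)
    n_phased_loci: int = 2
    phase_cycle: int = 21
    phase_cycles: int = 9
    phase_occupancy: int = 9  # occupied cycle slots in the planted register
    phase_noise_reads: int = 0  # off-register 21-nt reads per locus
    phase_reads_per_slot: int = 3
    # conservation model
    cons_background: float = 0.2
    cons_hotspot: float = 0.9
    cons_noise_sd: float = 0.05


@dataclass
class TruthManifest:
    """Planted ground truth for evaluating every downstream caller."""

    hotspots: list = field(default_factory=list)  # GenomicInterval
    diff_bins: list = field(default_factory=list)  # dict(interval, fold, assay)
    phased_loci: list = field(default_factory=list)  # dict(interval, register)
    feature_categories: dict = field(default_factory=dict)  # feature_id -> category


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict  # chrom -> sequence
    features: list  # AnnotationFeature
    libraries: dict  # name ("ds_a","ds_b","sm_a","sm_b") -> list[AlignedRead]
    conservation: ConservationTrack
    truth: TruthManifest


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _layout_nonoverlapping(
    rng: np.random.Generator, size: int, lengths: Sequence[int]
) -> list[int]:
    """Place segments of the given lengths in [0, size) with >= 1 nt gaps.

    The leftover space is distributed multinomially over the k+1 gaps, so
    realized segment lengths are exactly the requested ones and no two
    segments touch (they can never merge into one covered run).
    """
    k = len(lengths)
    total = int(sum(lengths))
    extra = size - total - (k + 1)
    if extra < 0:
        raise ValueError(
            f"planted elements exceed chromosome bounds: need {total + k + 1} > {size}"
        )
    gaps = 1 + rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
    starts: list[int] = []
    pos = 0
    for g, L in zip(gaps[:-1], lengths):
        pos += int(g)
        starts.append(pos)
        pos += int(L)
    return starts


def _tile_reads(
    chrom: str, start: int, length: int, read_len_cap: int, n_min: int, strand: str,
    alternate: bool, name_prefix: str,
) -> list[AlignedRead]:
    """Reads that cover [start, start+length) exactly, with >= n_min reads."""
    rl = min(length, read_len_cap)
    n = max(n_min, math.ceil((length - rl) / rl) + 1 if rl else 1, 2)
    reads = []
    for i in range(n):
        if n == 1:
            p = 0
        else:
            p = math.floor(i * (length - rl) / (n - 1))
        if i == n - 1:
            p = length - rl
        s = strand if not alternate else ("+" if i % 2 == 0 else "-")
        reads.append(
            AlignedRead(
                GenomicInterval(chrom, start + p, start + p + rl, s),
                name=f"{name_prefix}_{i}",
            )
        )
    return reads


def _random_genome(rng: np.random.Generator, sizes: Mapping[str, int]) -> dict[str, str]:
    alphabet = np.array(list("ACGT"))
    return {
        chrom: "".join(alphabet[rng.integers(0, 4, size=n)]) for chrom, n in sizes.items()
    }


def _place_features(
    rng: np.random.Generator, sizes: Mapping[str, int], layout: Mapping[str, tuple]
) -> list[AnnotationFeature]:
    features: list[AnnotationFeature] = []
    spec: list[tuple[str, int]] = []
    for category, (count, length) in layout.items():
        spec.extend((category, length) for _ in range(count))
    rng.shuffle(spec)
    chroms = list(sizes)
    positions = {c: 50 for c in chroms}
    ci = 0
    for k, (category, length) in enumerate(spec):
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            pos = positions[chrom]
            if pos + length + 50 <= sizes[chrom]:
                strand = "+" if k % 2 == 0 else "-"
                features.append(
                    AnnotationFeature(
                        GenomicInterval(chrom, pos, pos + length, strand),
                        category=category,
                        feature_id=f"{category}_{k}",
                    )
                )
                positions[chrom] = pos + length + 50
                placed = True
                break
        if not placed:
            raise ValueError("feature layout exceeds chromosome bounds")
    return features


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset plus its truth manifest.

    Components: genome sequence; annotation features; a background
    population of geometric-length covered segments with planted hotspot
    segments (read sets shared by the A and B dsRNA libraries, so they do
    not confound the differential comparison); per-bin Poisson background
    reads in all four libraries with the planted bins' library-A rate
    multiplied by the configured fold; planted phased loci inside the first
    planted differential bins; and a conservation track elevated inside
    hotspots. The same seed yields byte-identical outputs.
    """
    cfg = config
    rngs = _substreams(
        cfg.seed,
        ["genome", "features", "segments", "bins", "phase", "conservation"],
    )
    genome = _random_genome(rngs["genome"], cfg.chrom_sizes)
    features = _place_features(rngs["features"], cfg.chrom_sizes, cfg.feature_layout)
    truth = TruthManifest(
        feature_categories={f.feature_id: f.category for f in features}
    )
    libraries: dict[str, list[AlignedRead]] = {k: [] for k in ("ds_a", "ds_b", "sm_a", "sm_b")}

    _plant_segments(cfg, rngs["segments"], libraries, truth)
    _plant_differential(cfg, rngs["bins"], libraries, truth)
    _plant_phased(cfg, rngs["phase"], libraries, truth)
    conservation = _build_conservation(cfg, rngs["conservation"], truth)

    return SimulatedDataset(
        config=cfg,
        genome=genome,
        features=features,
        libraries=libraries,
        conservation=conservation,
        truth=truth,
    )


def _plant_segments(cfg, rng, libraries, truth) -> None:
    """Background geometric segments and planted hotspots (dsRNA libraries)."""
    total = cfg.n_background_segments + cfg.n_hotspots
    if total == 0:
        return
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=total, p=sizes / sizes.sum())
    is_hotspot = np.zeros(total, dtype=bool)
    if cfg.n_hotspots:
        is_hotspot[rng.choice(total, size=cfg.n_hotspots, replace=False)] = True
    bg_lengths = rng.geometric(1.0 / cfg.mean_segment_length, size=total)
    seg_id = 0
    for ci, chrom in enumerate(chroms):
        here = np.flatnonzero(assignment == ci)
        if here.size == 0:
            continue
        lengths = [
            cfg.hotspot_length if is_hotspot[i] else int(bg_lengths[i]) for i in here
        ]
        starts = _layout_nonoverlapping(rng, cfg.chrom_sizes[chrom], lengths)
        for i, start, L in zip(here, starts, lengths):
            alternate = bool(rng.random() < cfg.inter_fraction)
            strand = "+" if rng.random() < 0.5 else "-"
            reads = _tile_reads(
                chrom, start, L, cfg.max_read_length, cfg.reads_per_segment,
                strand, alternate, f"seg{seg_id}",
            )
            libraries["ds_a"].extend(reads)
            libraries["ds_b"].extend(reads)
            if is_hotspot[i]:
                truth.hotspots.append(GenomicInterval(chrom, start, start + L, "."))
            seg_id += 1
    truth.hotspots.sort()


def _plant_differential(cfg, rng, libraries, truth) -> None:
    """Per-bin Poisson background in all libraries; planted fold-change bins."""
    if cfg.mean_bin_weight <= 0:
        return
    from .differential import bin_genome

    bins = bin_genome(cfg.chrom_sizes, cfg.bin_width)
    full_bins = [b for b in bins if len(b.interval) >= cfg.bin_width]
    n_plant = min(cfg.n_diff_bins, len(full_bins))
    planted_idx = (
        rng.choice(len(full_bins), size=n_plant, replace=False) if n_plant else []
    )
    planted = {full_bins[int(i)].index for i in planted_idx}
    sm_lengths = np.array(list(cfg.smrna_length_weights), dtype=int)
    sm_probs = np.array(list(cfg.smrna_length_weights.values()), dtype=float)
    sm_probs = sm_probs / sm_probs.sum()
    rid = 0
    for b in bins:
        iv = b.interval
        boosted = b.index in planted
        # each bin expresses one short patch; its reads cluster there, so bin
        # counts carry the differential signal without saturating coverage
        span = min(cfg.bin_patch_span, len(iv))
        patch_start = int(rng.integers(iv.start, iv.end - span + 1))
        for assay, (lib_a, lib_b) in (
            ("dsRNA", ("ds_a", "ds_b")),
            ("smRNA", ("sm_a", "sm_b")),
        ):
            boost = cfg.diff_fold if boosted and cfg.diff_assay in (assay, "both") else 1.0
            for lib, rate in ((lib_a, cfg.mean_bin_weight * boost), (lib_b, cfg.mean_bin_weight)):
                n_reads = int(rng.poisson(rate))
                if assay == "dsRNA":
                    rls = np.full(n_reads, min(cfg.diff_read_length, span))
                else:
                    rls = np.minimum(
                        sm_lengths[rng.choice(sm_lengths.size, size=n_reads, p=sm_probs)],
                        span,
                    )
                starts = rng.integers(
                    patch_start, np.maximum(patch_start + span - rls, patch_start) + 1
                )
                strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
                for s, rl, st in zip(starts, rls, strands):
                    libraries[lib].append(
                        AlignedRead(
                            GenomicInterval(iv.chrom, int(s), int(s + rl), str(st)),
                            name=f"bin{rid}",
                        )
                    )
                    rid += 1
        if boosted:
            truth.diff_bins.append(
                {"interval": iv, "fold": cfg.diff_fold, "assay": cfg.diff_assay}
            )


def _plant_phased(cfg, rng, libraries, truth) -> None:
    """Phased 21-nt loci inside planted differential bins (or standalone)."""
    if cfg.n_phased_loci == 0:
        return
    span = cfg.phase_cycle * cfg.phase_cycles
    hosts: list[GenomicInterval] = [d["interval"] for d in truth.diff_bins]
    if len(hosts) < cfg.n_phased_loci:
        # standalone loci at fixed offsets on the first chromosome
        chrom = next(iter(cfg.chrom_sizes))
        size = cfg.chrom_sizes[chrom]
        needed = cfg.n_phased_loci - len(hosts)
        step = max(span + 100, size // (needed + 1))
        for i in range(needed):
            start = min(i * step, size - span)
            hosts.append(GenomicInterval(chrom, start, min(start + span, size), "."))
    for locus_i in range(cfg.n_phased_loci):
        host = hosts[locus_i]
        if len(host) < span:
            raise ValueError("phased locus exceeds its host interval")
        locus = GenomicInterval(host.chrom, host.start, host.start + span, "+")
        register = int(rng.integers(0, cfg.phase_cycle))
        slots = rng.choice(
            cfg.phase_cycles, size=min(cfg.phase_occupancy, cfg.phase_cycles), replace=False
        )
        for slot in sorted(int(s) for s in slots):
            pos = locus.start + slot * cfg.phase_cycle + register
            for _ in range(cfg.phase_reads_per_slot):
                libraries["sm_a"].append(
                    AlignedRead(
                        GenomicInterval(host.chrom, pos, pos + cfg.phase_cycle, "+"),
                        name=f"phased{locus_i}_{slot}",
                    )
                )
        for j in range(cfg.phase_noise_reads):
            off = int(rng.integers(0, span - cfg.phase_cycle))
            libraries["sm_a"].append(
                AlignedRead(
                    GenomicInterval(
                        host.chrom, locus.start + off, locus.start + off + cfg.phase_cycle, "+"
                    ),
                    name=f"phnoise{locus_i}_{j}",
                )
            )
        truth.phased_loci.append({"interval": locus, "register": register})


def _build_conservation(cfg, rng, truth) -> ConservationTrack:
    track = ConservationTrack(cfg.chrom_sizes)
    for chrom, size in cfg.chrom_sizes.items():
        base = cfg.cons_background + rng.normal(0.0, cfg.cons_noise_sd, size=size)
        track.scores[chrom] = np.clip(base, 0.0, 1.0)
    for iv in truth.hotspots:
        n = len(iv)
        vals = cfg.cons_hotspot + rng.normal(0.0, cfg.cons_noise_sd, size=n)
        track.scores[iv.chrom][iv.start : iv.end] = np.clip(vals, 0.0, 1.0)
    return track


# ---------------------------------------------------------------------------
# Call evaluation against the truth manifest
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Interval-recovery summary by >= 50% reciprocal overlap."""

    n_truth: int
    n_calls: int
    n_matched: int
    false_calls: int
    sensitivity: float
    matches: list = field(default_factory=list)  # (truth index, call index)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def evaluate_calls(
    calls: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> RecoveryReport:
    """Match called intervals to planted truth by reciprocal overlap.

    A truth element is recovered when some call overlaps it by at least
    ``min_reciprocal`` of both lengths; calls matching no truth element are
    false calls. Matching is deterministic (coordinate order, best overlap
    first).
    """
    matched_truth: set[int] = set()
    matched_calls: set[int] = set()
    matches: list[tuple[int, int]] = []
    for ti, t in enumerate(truth):
        best, best_ro = None, min_reciprocal
        for ci, c in enumerate(calls):
            ro = _reciprocal_overlap(t, c)
            if ro >= best_ro and (best is None or ro > best_ro):
                best, best_ro = ci, ro
        if best is not None:
            matched_truth.add(ti)
            matched_calls.add(best)
            matches.append((ti, best))
    false_calls = sum(
        1
        for ci, c in enumerate(calls)
        if not any(_reciprocal_overlap(t, c) >= min_reciprocal for t in truth)
    )
    return RecoveryReport(
        n_truth=len(truth),
        n_calls=len(calls),
        n_matched=len(matched_truth),
        false_calls=false_calls,
        sensitivity=len(matched_truth) / len(truth) if truth else 1.0,
        matches=matches,
    )


# ---------------------------------------------------------------------------
# On-disk export
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write all dataset components (FASTA, GFF3, BED, bedGraph, truth TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(dataset.genome, paths["genome"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(dataset.config.chrom_sizes, paths["chrom_sizes"])
    paths["annotation"] = outdir / "annotation.gff3"
    write_gff3(dataset.features, paths["annotation"])
    for name, reads in dataset.libraries.items():
        paths[name] = outdir / f"{name}.bed"
        write_bed(reads, paths[name])
    paths["conservation"] = outdir / "conservation.bedgraph"
    write_cons_bedgraph(dataset.conservation, paths["conservation"])
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tchrom\tstart\tend\tdetail\n")
        for iv in dataset.truth.hotspots:
            fh.write(f"hotspot\t{iv.chrom}\t{iv.start}\t{iv.end}\t.\n")
        for d in dataset.truth.diff_bins:
            iv = d["interval"]
            fh.write(
                f"diff_bin\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"fold={d['fold']};assay={d['assay']}\n"
            )
        for d in dataset.truth.phased_loci:
            iv = d["interval"]
            fh.write(
                f"phased_locus\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"register={d['register']}\n"
            )
    return paths
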