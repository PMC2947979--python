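"""Detection of 21-nt phased siRNA production at candidate loci.

Processive dicing of an RDR-made double-stranded precursor from a defined
end releases small RNAs whose 5' ends fall on one residue class modulo the
cycle length D (21 nt for DCL4 products). Within a window of m cycles
(m x D slots), each slot is the (cycle, register) cell of a 5' end; the
phasing statistic asks whether the occupied slots concentrate in one of the
D registers far beyond chance. The test is the hypergeometric upper tail of
drawing >= k of the n occupied slots in the m slots of one register out of
m x D, Bonferroni-corrected across the D registers (a Howell-style
slot-occupancy test). Minus-strand 5' ends are shifted +2 nt before taking
the modulus, matching the 2-nt 3' overhang of sRNA duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_io import AlignedRead, GenomicInterval
from .differential import SubstrateCall

DEFAULT_CYCLE = 21
DEFAULT_CYCLES = 9
DEFAULT_ANTISENSE_OFFSET = 2
DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_MIN_SLOTS = 4
DEFAULT_SIZE_RANGE = (20, 22)


@dataclass
class PhasingScore:
    """Result of the slot-occupancy test on one window."""

    best_register: int
    k: int  # occupied slots in the best register
    n: int  # occupied slots in the whole window
    p_value: float  # Bonferroni-adjusted over the D registers
    window: GenomicInterval | None = None


def five_prime_position(read: AlignedRead) -> int:
    """Genomic coordinate of the read's 5' end (strand-aware)."""
    iv = read.interval
    return iv.start if iv.strand != "-" else iv.end - 1


def register_positions(
    reads: Iterable[AlignedRead],
    locus: GenomicInterval,
    cycle: int = DEFAULT_CYCLE,
    cycles: int | None = None,
    antisense_offset: int = DEFAULT_ANTISENSE_OFFSET,
    size_range: tuple[int, int] | None = DEFAULT_SIZE_RANGE,
) -> np.ndarray:
    """Slot occupancy per register for reads whose 5' ends fall in a window.

    The window spans ``cycles x cycle`` bases from ``locus.start`` (all full
    cycles in the locus when ``cycles`` is None). A slot is the (cycle,
    register) cell of a 5' end offset; minus-strand 5' ends are shifted by
    ``antisense_offset`` before the modulus. Returns, for each of the
    ``cycle`` registers, the number of distinct occupied cycle slots;
    duplicate 5' ends and read order do not matter. Reads outside
    ``size_range`` are ignored when a range is given.
    """
    if len(locus) < cycle:
        raise ValueError(f"locus shorter than one cycle ({len(locus)} < {cycle})")
    m = cycles if cycles is not None else len(locus) // cycle
    span = m * cycle
    occupied = np.zeros((cycle, m), dtype=bool)
    for read in reads:
        iv = read.interval
        if iv.chrom != locus.chrom:
            continue
        if size_range is not None and not (size_range[0] <= len(iv) <= size_range[1]):
            continue
        pos = five_prime_position(read)
        offset = pos - locus.start
        if iv.strand == "-":
            offset += antisense_offset
        if not (0 <= offset < span):
            continue
        occupied[offset % cycle, offset // cycle] = True
    return occupied.sum(axis=1).astype(int)


def phasing_pvalue(occupancy: Sequence[int], m: int, cycle: int = DEFAULT_CYCLE) -> PhasingScore:
    """Hypergeometric slot-occupancy test with Bonferroni over registers.

    With n occupied slots among the ``m * cycle`` slots of the window and k
    of them in the best register (m slots), the p-value is
    ``P(K >= k) x cycle`` under the hypergeometric null, capped at 1.
    """
    occupancy = np.asarray(occupancy, dtype=int)
    if occupancy.shape != (cycle,):
        raise ValueError(f"occupancy must have one entry per register ({cycle})")
    if (occupancy > m).any() or (occupancy < 0).any():
        raise ValueError("register occupancy must lie in [0, m]")
    n = int(occupancy.sum())
    if n == 0:
        raise ValueError("no occupied slots: no reads to test")
    best = int(np.argmax(occupancy))
    k = int(occupancy[best])
    p = float(hypergeom.sf(k - 1, m * cycle, m, n))
    return PhasingScore(best_register=best, k=k, n=n, p_value=min(1.0, p * cycle))


def score_locus(
    reads: Sequence[AlignedRead],
    locus: GenomicInterval,
    cycle: int = DEFAULT_CYCLE,
    cycles: int = DEFAULT_CYCLES,
    antisense_offset: int = DEFAULT_ANTISENSE_OFFSET,
    min_slots: int = DEFAULT_MIN_SLOTS,
    size_range: tuple[int, int] | None = DEFAULT_SIZE_RANGE,
) -> PhasingScore | None:
    """Best (smallest-p) phasing window across a locus, slid in cycle steps.

    Windows of ``cycles`` full cycles are scanned; at a locus shorter than
    one window, a single truncated window of all full cycles is used.
    Windows with fewer than ``min_slots`` occupied slots are not tested.
    Returns None when no window is testable.
    """
    span = cycles * cycle
    if len(locus) < cycle:
        raise ValueError("locus shorter than one cycle")
    if len(locus) < span:
        m = len(locus) // cycle
        starts = [locus.start]
    else:
        m = cycles
        starts = list(range(locus.start, locus.end - span + 1, cycle))
    best: PhasingScore | None = None
    for s in starts:
        window = GenomicInterval(locus.chrom, s, s + m * cycle, locus.strand)
        occ = register_positions(
            reads, window, cycle=cycle, cycles=m,
            antisense_offset=antisense_offset, size_range=size_range,
        )
        n = int(occ.sum())
        if n < min_slots:
            continue
        score = phasing_pvalue(occ, m, cycle)
        score.window = window
        if best is None or score.p_value < best.p_value:
            best = score
    return best


def call_phased(
    substrates: Sequence[SubstrateCall],
    smrna_reads: Sequence[AlignedRead],
    cycle: int = DEFAULT_CYCLE,
    cycles: int = DEFAULT_CYCLES,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_slots: int = DEFAULT_MIN_SLOTS,
    antisense_offset: int = DEFAULT_ANTISENSE_OFFSET,
    size_range: tuple[int, int] | None = DEFAULT_SIZE_RANGE,
) -> list[tuple[SubstrateCall, PhasingScore | None]]:
    """Annotate substrate calls as phased / non-phased.

    A substrate is phased when its best window's Bonferroni-adjusted
    p-value is at or below ``p_threshold``; loci without testable windows
    (no small-RNA reads, or too few occupied slots) are non-phased with a
    None score ("no data"). Mutates each substrate's ``phased`` flag and
    returns (substrate, best score) pairs.
    """
    results: list[tuple[SubstrateCall, PhasingScore | None]] = []
    for sub in substrates:
        locus = sub.ds_call.region or sub.bin.interval
        score = score_locus(
            smrna_reads, locus, cycle=cycle, cycles=cycles,
            antisense_offset=antisense_offset, min_slots=min_slots,
            size_range=size_range,
        )
        sub.phased = score is not None and score.p_value <= p_threshold
        results.append((sub, score))
    return results
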