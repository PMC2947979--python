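"""Coverage-constrained RNA secondary-structure models.

Read coverage from a duplex-enriched library marks bases that were
base-paired in vivo: any transcript position covered by at least one mapped
read is constrained as paired ('|' in the constraint string) and all other
positions are left unconstrained ('.'). The constrained and unconstrained
structures of a transcript are then computed with a folding engine — either
the ViennaRNA thermodynamic engine (minimum free energy, kcal/mol) through
its Python bindings, or a builtin constrained Nussinov maximum-base-pairing
engine that requires no external dependency and is exhaustively verifiable
on short sequences. Per-base read densities, normalized by the number of
covered nucleotides of the transcript, are attached for rendering and
export (CT / dot-bracket).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import CoverageTrack, GenomicInterval

MIN_LOOP = 3
#: Watson-Crick plus wobble pairs.
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class ConstraintInfeasibleError(ValueError):
    """Raised when '|' (must-pair) positions cannot all be paired."""

    def __init__(self, positions: Sequence[int], engine: str):
        self.positions = list(positions)
        super().__init__(
            f"{engine}: constraint infeasible; must-pair positions without an "
            f"admissible partner: {self.positions}"
        )


class EngineUnavailableError(RuntimeError):
    """Raised when the requested folding engine cannot be loaded."""


@dataclass
class StructureModel:
    """A folded transcript with constraint provenance and read densities."""

    transcript_id: str
    sequence: str
    dotbracket: str
    pair_table: list  # per position: partner index (0-based) or None
    score: float  # free energy (kcal/mol, vienna) or pair count (builtin)
    engine: str = "builtin"
    constrained: bool = False
    constraints: str | None = None
    densities: np.ndarray | None = None

    def __post_init__(self):
        if len(self.dotbracket) != len(self.sequence):
            raise ValueError("dot-bracket length must equal sequence length")
        for i, j in enumerate(self.pair_table):
            if j is not None and self.pair_table[j] != i:
                raise ValueError("pair table not symmetric")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table) if j is not None and i < j)


def coverage_to_constraints(
    transcript: GenomicInterval, track: CoverageTrack
) -> str:
    """Constraint string for a transcript: '|' exactly where coverage > 0.

    Coverage is taken from the transcript's strand; for minus-strand
    transcripts the genomic window is reversed so the string runs 5' to 3'
    along the transcript.
    """
    depth = track.depth(transcript.chrom, transcript.strand)[
        transcript.start : transcript.end
    ]
    if transcript.strand == "-":
        depth = depth[::-1]
    return "".join("|" if d > 0 else "." for d in depth)


def pairs_to_dotbracket(pair_table: Sequence, n: int) -> str:
    out = ["."] * n
    for i, j in enumerate(pair_table):
        if j is not None and i < j:
            out[i], out[j] = "(", ")"
    return "".join(out)


def dotbracket_to_pairs(dotbracket: str) -> list:
    """Pair table from a dot-bracket string; unbalanced input raises."""
    stack: list[int] = []
    table: list = [None] * len(dotbracket)
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return table


def _check_constraints(seq: str, constraints: str | None) -> None:
    if constraints is None:
        return
    if len(constraints) != len(seq):
        raise ValueError(
            f"constraint length {len(constraints)} != sequence length {len(seq)}"
        )
    bad = set(constraints) - {"|", "."}
    if bad:
        raise ValueError(f"invalid constraint characters {sorted(bad)}")


def nussinov_fold(
    seq: str,
    constraints: str | None = None,
    min_loop: int = MIN_LOOP,
    allowed_pairs: frozenset = ALLOWED_PAIRS,
    transcript_id: str = "seq",
) -> StructureModel:
    """Maximum-base-pair folding with must-pair constraints (Nussinov DP).

    Maximizes the number of allowed pairs (Watson-Crick plus wobble by
    default) subject to a minimum hairpin loop of ``min_loop`` bases and to
    the requirement that every '|' position be paired. The traceback is
    deterministic: position i pairs with the smallest admissible partner j
    that achieves the optimum, and pairing is preferred over leaving i
    unpaired on ties. Infeasible constraints raise
    :class:`ConstraintInfeasibleError` rather than being silently relaxed.
    """
    seq = seq.upper().replace("T", "U")
    _check_constraints(seq, constraints)
    n = len(seq)
    must = [constraints is not None and constraints[i] == "|" for i in range(n)]

    def can_pair(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in allowed_pairs and j - i - 1 >= min_loop

    # pre-check: every must-pair position needs at least one admissible partner
    orphans = [
        i for i in range(n) if must[i] and not any(can_pair(*sorted((i, j))) for j in range(n) if j != i)
    ]
    if orphans:
        raise ConstraintInfeasibleError(orphans, "builtin-nussinov")

    NEG = float("-inf")
    # N[i][j]: max pairs in seq[i..j]; -inf if constraints infeasible there.
    # A single must-pair base alone in an interval is infeasible (diagonal).
    N = [[0.0] * n for _ in range(n)]
    for i in range(n):
        N[i][i] = NEG if must[i] else 0.0

    def sub(a: int, b: int) -> float:
        return N[a][b] if a <= b else 0.0

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j] if not must[i] else NEG
            for k in range(i + min_loop + 1, j + 1):
                if not can_pair(i, k):
                    continue
                inner, rest = sub(i + 1, k - 1), sub(k + 1, j)
                if inner > NEG and rest > NEG:
                    best = max(best, 1.0 + inner + rest)
            N[i][j] = best
    total = N[0][n - 1] if n > 1 else (NEG if n == 1 and must[0] else 0.0)
    if total == NEG:
        raise ConstraintInfeasibleError(
            [i for i in range(n) if must[i]], "builtin-nussinov"
        )

    pair_table: list = [None] * n
    stack = [(0, n - 1)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i][j]
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            if not can_pair(i, k):
                continue
            inner = N[i + 1][k - 1] if i + 1 <= k - 1 else 0.0
            rest = N[k + 1][j] if k + 1 <= j else 0.0
            if inner > NEG and rest > NEG and 1.0 + inner + rest == target:
                chosen = k
                break
        if chosen is not None:
            pair_table[i], pair_table[chosen] = chosen, i
            if i + 1 <= chosen - 1:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))
        else:
            # i stays unpaired (feasible because N[i][j] > -inf and no pair won)
            stack.append((i + 1, j))
    return StructureModel(
        transcript_id=transcript_id,
        sequence=seq,
        dotbracket=pairs_to_dotbracket(pair_table, n),
        pair_table=pair_table,
        score=float(int(total)) if total > NEG else 0.0,
        engine="builtin",
        constrained=constraints is not None and "|" in constraints,
        constraints=constraints,
    )


def vienna_fold(
    seq: str, constraints: str | None = None, transcript_id: str = "seq"
) -> StructureModel:
    """Minimum-free-energy folding through the ViennaRNA Python bindings.

    The constraint string is passed verbatim in the Vienna constraint
    dialect ('|' = must pair, '.' = unconstrained) and enforced; a result
    leaving a '|' position unpaired raises
    :class:`ConstraintInfeasibleError`.
    """
    seq = seq.upper().replace("T", "U")
    _check_constraints(seq, constraints)
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise EngineUnavailableError(
            "thermodynamic engine unavailable: the ViennaRNA Python bindings "
            "('RNA') are not installed; use engine='builtin' or install ViennaRNA"
        ) from exc
    fc = RNA.fold_compound(seq)
    if constraints is not None and "|" in constraints:
        fc.hc_add_from_db(constraints, RNA.CONSTRAINT_DB_DEFAULT | RNA.CONSTRAINT_DB_ENFORCE_BP)
    dotbracket, mfe = fc.mfe()
    pair_table = dotbracket_to_pairs(dotbracket)
    if constraints is not None:
        unmet = [i for i, c in enumerate(constraints) if c == "|" and pair_table[i] is None]
        if unmet:
            raise ConstraintInfeasibleError(unmet, "vienna")
    return StructureModel(
        transcript_id=transcript_id,
        sequence=seq,
        dotbracket=dotbracket,
        pair_table=pair_table,
        score=float(mfe),
        engine="vienna",
        constrained=constraints is not None and "|" in constraints,
        constraints=constraints,
    )


ENGINES = {"builtin": nussinov_fold, "vienna": vienna_fold}


def fold(
    seq: str,
    constraints: str | None = None,
    engine: str = "builtin",
    transcript_id: str = "seq",
    **kwargs,
) -> StructureModel:
    """Fold a transcript with the selected engine (builtin or vienna)."""
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    return ENGINES[engine](seq, constraints, transcript_id=transcript_id, **kwargs)


def project_reads(
    model: StructureModel, transcript: GenomicInterval, track: CoverageTrack
) -> np.ndarray:
    """Attach per-base read density normalized by covered transcript length.

    density(i) = depth(i) / (number of covered nucleotides in the
    transcript); with zero coverage all densities are zero.
    """
    depth = track.depth(transcript.chrom, transcript.strand)[
        transcript.start : transcript.end
    ].copy()
    if transcript.strand == "-":
        depth = depth[::-1]
    if len(depth) != len(model.sequence):
        raise ValueError("transcript length does not match model sequence")
    covered = int((depth > 0).sum())
    densities = depth / covered if covered else np.zeros_like(depth)
    model.densities = densities
    return densities


# ---------------------------------------------------------------------------
# Structure exchange formats
# ---------------------------------------------------------------------------

def write_ct(model: StructureModel, path) -> None:
    """Write a connect-table (CT) file for the model."""
    n = len(model.sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\t{model.transcript_id} score={model.score:g} engine={model.engine}\n")
        for i in range(n):
            partner = model.pair_table[i]
            fh.write(
                f"{i + 1}\t{model.sequence[i]}\t{i}\t{(i + 2) if i + 1 < n else 0}\t"
                f"{(partner + 1) if partner is not None else 0}\t{i + 1}\n"
            )


def read_ct(path) -> StructureModel:
    """Read a CT file back into a model (inverse of :func:`write_ct`)."""
    with open(path) as fh:
        header = fh.readline().split("\t")
        n = int(header[0])
        title = header[1].strip() if len(header) > 1 else "seq"
        transcript_id = title.split()[0] if title else "seq"
        score = 0.0
        engine = "builtin"
        for tok in title.split():
            if tok.startswith("score="):
                score = float(tok[6:])
            elif tok.startswith("engine="):
                engine = tok[7:]
        seq_chars = [""] * n
        pair_table: list = [None] * n
        for line in fh:
            parts = line.split()
            if len(parts) < 6:
                continue
            i = int(parts[0]) - 1
            seq_chars[i] = parts[1]
            partner = int(parts[4])
            pair_table[i] = partner - 1 if partner else None
    seq = "".join(seq_chars)
    return StructureModel(
        transcript_id=transcript_id,
        sequence=seq,
        dotbracket=pairs_to_dotbracket(pair_table, n),
        pair_table=pair_table,
        score=score,
        engine=engine,
    )


def write_dotbracket(model: StructureModel, path) -> None:
    """FASTA-style dot-bracket export with the score on the header line."""
    with open(path, "w") as fh:
        fh.write(f">{model.transcript_id} score={model.score:g} engine={model.engine}\n")
        fh.write(model.sequence + "\n")
        fh.write(model.dotbracket + "\n")


def read_dotbracket(path) -> StructureModel:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(">"):
            raise ValueError("missing dot-bracket header line")
        fields = header[1:].split()
        transcript_id = fields[0] if fields else "seq"
        score = 0.0
        engine = "builtin"
        for tok in fields[1:]:
            if tok.startswith("score="):
                score = float(tok[6:])
            elif tok.startswith("engine="):
                engine = tok[7:]
        seq = fh.readline().strip()
        dotbracket = fh.readline().strip()
    pair_table = dotbracket_to_pairs(dotbracket)  # raises on unbalanced input
    return StructureModel(
        transcript_id=transcript_id,
        sequence=seq,
        dotbracket=dotbracket,
        pair_table=pair_table,
        score=score,
        engine=engine,
    )
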