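"""Coverage constraints, Nussinov/Vienna folding, and structure file formats."""

import numpy as np
import pytest

from dsrnatk import (
    ConstraintInfeasibleError,
    GenomicInterval,
    build_coverage,
    coverage_to_constraints,
    fold,
    nussinov_fold,
    project_reads,
    read_ct,
    read_dotbracket,
    vienna_fold,
    write_ct,
    write_dotbracket,
)
from dsrnatk.structure import ALLOWED_PAIRS, dotbracket_to_pairs

from conftest import read


class TestCoverageToConstraints:
    def test_covered_positions_marked_paired(self, chrom_sizes):
        track = build_coverage([read("chr1", 101, 103, "+")], chrom_sizes)
        tx = GenomicInterval("chr1", 100, 104, "+")
        assert coverage_to_constraints(tx, track) == ".||."

    def test_zero_coverage_all_unconstrained(self, chrom_sizes):
        track = build_coverage([], chrom_sizes)
        tx = GenomicInterval("chr1", 0, 10, "+")
        assert coverage_to_constraints(tx, track) == "." * 10

    def test_full_coverage_all_paired(self, chrom_sizes):
        track = build_coverage([read("chr1", 0, 10, "+")], chrom_sizes)
        tx = GenomicInterval("chr1", 0, 10, "+")
        assert coverage_to_constraints(tx, track) == "|" * 10

    def test_minus_strand_reversed_and_strand_specific(self, chrom_sizes):
        # plus-strand reads must not constrain a minus-strand transcript
        track = build_coverage(
            [read("chr1", 100, 102, "-"), read("chr1", 108, 110, "+")], chrom_sizes
        )
        tx = GenomicInterval("chr1", 100, 110, "-")
        # transcript 5'->3' runs from genomic end to start
        assert coverage_to_constraints(tx, track) == "........||"

    def test_exhaustive_per_base_rule(self, chrom_sizes):
        rng = np.random.default_rng(71)
        reads = [read("chr1", int(s), int(s) + int(l), "+")
                 for s, l in zip(rng.integers(0, 450, 40), rng.integers(1, 30, 40))]
        track = build_coverage(reads, chrom_sizes)
        tx = GenomicInterval("chr1", 0, 500, "+")
        constraints = coverage_to_constraints(tx, track)
        depth = track.plus["chr1"][:500]
        for i in range(500):
            assert (constraints[i] == "|") == (depth[i] > 0)


def brute_force_max_pairs(seq, constraints=None, min_loop=3):
    """Exhaustive enumeration of all nested structures; None if infeasible."""
    n = len(seq)
    must = [constraints is not None and constraints[i] == "|" for i in range(n)]

    def rec(positions):
        if not positions:
            return 0
        i, rest = positions[0], positions[1:]
        best = None
        if not must[i]:
            sub = rec(rest)
            if sub is not None:
                best = sub
        for idx, j in enumerate(rest):
            if (seq[i], seq[j]) in ALLOWED_PAIRS and j - i - 1 >= min_loop:
                # nested: partners of i must not cross the (i, j) arc
                inside = tuple(p for p in rest[:idx] if i < p < j)
                outside = tuple(p for p in rest[idx + 1:] if p > j)
                a, b = rec(inside), rec(outside)
                if a is not None and b is not None:
                    cand = 1 + a + b
                    if best is None or cand > best:
                        best = cand
        return best

    return rec(tuple(range(n)))


class TestNussinov:
    def test_no_pairs_possible(self):
        model = nussinov_fold("AAAA")
        assert model.dotbracket == "...."
        assert model.n_pairs == 0

    def test_triple_helix_stem(self):
        model = nussinov_fold("GGGAAACCC")
        assert model.n_pairs == 3
        # deterministic traceback: G1-C9, G2-C8, G3-C7 (0-based 0-8, 1-7, 2-6)
        assert model.pair_table[0] == 8
        assert model.pair_table[1] == 7
        assert model.pair_table[2] == 6
        assert model.dotbracket == "(((...)))"

    def test_min_loop_enforced(self):
        with pytest.raises(ConstraintInfeasibleError):
            nussinov_fold("GCGC", "||||", min_loop=3)
        model = nussinov_fold("GCGC", "||||", min_loop=0)
        assert model.n_pairs == 2

    def test_unpairable_constraint_position(self):
        with pytest.raises(ConstraintInfeasibleError) as err:
            nussinov_fold("AAAA", "|...")
        assert 0 in err.value.positions

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(73)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            model = nussinov_fold(seq)
            assert model.n_pairs == brute_force_max_pairs(seq)

    def test_constrained_matches_enumeration_or_raises(self):
        rng = np.random.default_rng(79)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            constraints = "".join(
                "|" if rng.random() < 0.3 else "." for _ in range(n)
            )
            expected = brute_force_max_pairs(seq, constraints)
            if expected is None:
                with pytest.raises(ConstraintInfeasibleError):
                    nussinov_fold(seq, constraints)
            else:
                model = nussinov_fold(seq, constraints)
                assert model.n_pairs == expected
                for i, c in enumerate(constraints):
                    if c == "|":
                        assert model.pair_table[i] is not None
                checked += 1
        assert checked > 5

    def test_all_dots_equals_unconstrained(self):
        for seq in ("GGGAAACCC", "GCAUGCAUGCAU", "AUAUAUAUAU"):
            free = nussinov_fold(seq)
            dotted = nussinov_fold(seq, "." * len(seq))
            assert free.dotbracket == dotted.dotbracket
            assert free.score == dotted.score

    def test_pairs_respect_alphabet_and_loop(self):
        rng = np.random.default_rng(83)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 30))
            model = nussinov_fold(seq)
            for i, j in enumerate(model.pair_table):
                if j is not None and i < j:
                    assert (seq[i], seq[j]) in ALLOWED_PAIRS
                    assert j - i - 1 >= 3


class TestViennaEngine:
    def test_mfe_fold_returns_negative_energy(self):
        model = vienna_fold("GGGGGAAACCCCCAAAGGGGGAAACCCCC")
        assert model.engine == "vienna"
        assert model.score < 0
        assert len(model.dotbracket) == 29

    def test_all_dots_bit_identical_to_unconstrained(self):
        seq = "GCGCUUCGGCGCAUAGCUAGCUAGC"
        free = fold(seq, engine="vienna")
        dotted = fold(seq, "." * len(seq), engine="vienna")
        assert free.dotbracket == dotted.dotbracket
        assert free.score == dotted.score

    def test_must_pair_positions_paired(self):
        seq = "GGGGGAAAACCCCC"
        constraints = "||........||.."
        model = vienna_fold(seq, constraints)
        for i, c in enumerate(constraints):
            if c == "|":
                assert model.pair_table[i] is not None

    def test_constraint_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            vienna_fold("GGGAAACCC", "...")

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="unknown engine"):
            fold("ACGU", engine="mfold")


class TestProjectReads:
    def test_uniform_density(self, chrom_sizes):
        track = build_coverage([read("chr1", 0, 8, "+", copies=2)], chrom_sizes)
        tx = GenomicInterval("chr1", 0, 8, "+")
        model = nussinov_fold("GGGAAACC", transcript_id="t1")
        dens = project_reads(model, tx, track)
        assert np.allclose(dens, 2.0 / 8)

    def test_zero_coverage_zeros(self, chrom_sizes):
        track = build_coverage([], chrom_sizes)
        tx = GenomicInterval("chr1", 0, 8, "+")
        model = nussinov_fold("GGGAAACC")
        assert np.allclose(project_reads(model, tx, track), 0.0)

    def test_mixed_depth_matches_division(self, chrom_sizes):
        track = build_coverage(
            [read("chr1", 0, 4, "+"), read("chr1", 2, 6, "+")], chrom_sizes
        )
        tx = GenomicInterval("chr1", 0, 8, "+")
        model = nussinov_fold("GGGAAACC")
        dens = project_reads(model, tx, track)
        depth = track.plus["chr1"][:8]
        assert np.allclose(dens, depth / 6)  # 6 covered nucleotides


class TestStructureFormats:
    def test_ct_round_trip(self, tmp_path):
        model = nussinov_fold("GGGAAACCC", transcript_id="hairpin1")
        p = tmp_path / "m.ct"
        write_ct(model, p)
        back = read_ct(p)
        assert back.sequence == model.sequence
        assert back.pair_table == model.pair_table
        assert back.score == model.score
        assert back.transcript_id == "hairpin1"

    def test_unpaired_only_ct(self, tmp_path):
        model = nussinov_fold("AAAA")
        p = tmp_path / "m.ct"
        write_ct(model, p)
        assert all(line.split()[4] == "0" for line in p.read_text().splitlines()[1:])

    def test_dotbracket_round_trip(self, tmp_path):
        rng = np.random.default_rng(89)
        for k in range(5):
            seq = "".join(rng.choice(list("ACGU"), 25))
            model = nussinov_fold(seq, transcript_id=f"t{k}")
            p = tmp_path / f"m{k}.db"
            write_dotbracket(model, p)
            back = read_dotbracket(p)
            assert (back.sequence, back.dotbracket, back.score) == (
                model.sequence, model.dotbracket, model.score
            )
            assert back.pair_table == model.pair_table

    def test_unbalanced_dotbracket_rejected(self, tmp_path):
        p = tmp_path / "bad.db"
        p.write_text(">x score=0\nACGU\n(()\n")
        with pytest.raises(ValueError, match="unbalanced"):
            read_dotbracket(p)
        with pytest.raises(ValueError):
            dotbracket_to_pairs("())")
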