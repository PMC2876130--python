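import pytest

from oracles import brute_force_forest_score, forest_to_tuples
from planac.folding import mfe_fold
from planac.io_formats import Sequence
from planac.structalign import (
    ForestScore,
    forest_align_score,
    forest_from_structure,
    implied_sequence_alignment,
    multiple_structure_align,
    pairwise_forest_align,
    structure_from_forest,
)

from conftest import random_rna


def random_structure(rng, length):
    """A random nested structure via stochastic bracket insertion."""
    db = ["."] * length
    for _ in range(length // 3):
        i = int(rng.integers(0, length))
        j = int(rng.integers(0, length))
        i, j = min(i, j), max(i, j)
        if j - i - 1 < 3:
            continue
        if all(db[k] == "." for k in (i, j)):
            # keep nestedness: only place if balanced inside
            depth = 0
            ok = True
            for k in range(i + 1, j):
                depth += {"(": 1, ")": -1, ".": 0}[db[k]]
                if depth < 0:
                    ok = False
                    break
            if ok and depth == 0:
                db[i], db[j] = "(", ")"
    return "".join(db)


class TestForestEncoding:
    def test_paper_example_shape(self, toy_pair):
        (s1, db1), _ = toy_pair
        f = forest_from_structure(s1, db1)
        kinds = [n.kind for n in f.roots]
        assert kinds == ["U", "U", "P", "U", "U"]
        pair = f.roots[2]
        assert pair.entries[0] == ("G", "C")
        assert [c.kind for c in pair.children] == ["P"]
        inner = pair.children[0]
        assert inner.entries[0] == ("G", "C")
        assert [c.kind for c in inner.children] == ["U"] * 4
        # node count law: #U + 2#P == sequence length
        assert f.size() == 12 - 2  # 8 U nodes + 2 P nodes

    def test_two_unpaired(self):
        f = forest_from_structure(Sequence("x", "AC"), "..")
        assert [n.kind for n in f.roots] == ["U", "U"]

    def test_unpaired_only_depth_one(self):
        f = forest_from_structure(Sequence("x", "ACGUA"), ".....")
        assert len(f.roots) == 5
        assert all(not n.children for n in f.roots)

    def test_round_trip(self, rng):
        for _ in range(20):
            seq = random_rna(rng, 15)
            db = random_structure(rng, 15)
            f = forest_from_structure(Sequence("x", seq), db)
            assert structure_from_forest(f) == (seq, db)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            forest_from_structure(Sequence("x", "ACGU"), "...")


class TestForestScoreType:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ForestScore(pair_match=-3.0, pair_gap=-2.0)
        with pytest.raises(ValueError):
            ForestScore(base_match=0.0, base_mismatch=1.0)


class TestPairwiseForestAlign:
    def test_self_alignment_is_all_match(self, rng):
        for _ in range(5):
            seq = random_rna(rng, 12)
            db = random_structure(rng, 12)
            f = forest_from_structure(Sequence("x", seq), db)
            g = forest_from_structure(Sequence("y", seq), db)
            y, score = pairwise_forest_align(f, g)
            aln = implied_sequence_alignment(y)
            assert aln.row(0) == aln.row(1) == seq
            assert score == brute_force_forest_score(
                forest_to_tuples(f), forest_to_tuples(f)
            )

    def test_toy_example_two_gaps_pair_to_pair(self, toy_pair):
        (s1, db1), (s2, db2) = toy_pair
        f1 = forest_from_structure(s1, db1)
        f2 = forest_from_structure(s2, db2)
        y, score = pairwise_forest_align(f1, f2)
        aln = implied_sequence_alignment(y)
        assert sum(row.count("-") for _, row in aln.rows) == 2
        assert aln.n_cols == 12
        # the shared pair is aligned pair-to-pair: some aligned column
        # pair is an open/close bracket with residues in both rows
        matched_pairs = [
            entries for kind, entries in y.columns()
            if kind == "open" and all(e is not None for e in entries)
        ]
        assert len(matched_pairs) == 1

    def test_matches_bruteforce_small_forests(self, rng):
        checked = 0
        while checked < 12:
            n = int(rng.integers(2, 9))
            seq = random_rna(rng, n)
            db = random_structure(rng, n)
            m = int(rng.integers(2, 9))
            seq2 = random_rna(rng, m)
            db2 = random_structure(rng, m)
            f1 = forest_from_structure(Sequence("a", seq), db)
            f2 = forest_from_structure(Sequence("b", seq2), db2)
            if f1.size() > 8 or f2.size() > 8:
                continue
            _, score = pairwise_forest_align(f1, f2)
            expected = brute_force_forest_score(
                forest_to_tuples(f1), forest_to_tuples(f2)
            )
            assert score == pytest.approx(expected), (seq, db, seq2, db2)
            checked += 1

    def test_symmetry(self, rng):
        for _ in range(5):
            f1 = forest_from_structure(
                Sequence("a", random_rna(rng, 14)), random_structure(rng, 14)
            )
            f2 = forest_from_structure(
                Sequence("b", random_rna(rng, 11)), random_structure(rng, 11)
            )
            assert forest_align_score(f1, f2) == pytest.approx(
                forest_align_score(f2, f1)
            )

    def test_projection_recovers_inputs(self, rng):
        for _ in range(10):
            f1 = forest_from_structure(
                Sequence("a", random_rna(rng, 12)), random_structure(rng, 12)
            )
            f2 = forest_from_structure(
                Sequence("b", random_rna(rng, 9)), random_structure(rng, 9)
            )
            y, _ = pairwise_forest_align(f1, f2)
            assert y.project(0) == structure_from_forest(f1)
            assert y.project(1) == structure_from_forest(f2)


class TestCompensatorySignal:
    def test_compensatory_change_score_invariant(self):
        s1 = Sequence("a", "AAGGAAAACCAA")
        db = "..((....)).."
        # compensatory: both partners of the inner pair swapped CG->AU
        s2 = Sequence("b", "AAGAAAAAUCAA")
        f1 = forest_from_structure(s1, db)
        f2 = forest_from_structure(s2, db)
        base = forest_align_score(f1, f1)
        assert forest_align_score(f1, f2) == pytest.approx(base)

    def test_pair_breaking_lowers_score(self, model):
        # one-sided substitution: the pair cannot form, topology changes
        s1 = Sequence("a", "GGGGAAAACCCC")
        s2 = Sequence("b", "GGGAAAAACCCC")  # breaks one pair
        f1 = forest_from_structure(s1, mfe_fold(s1, model).dotbracket)
        f2 = forest_from_structure(s2, mfe_fold(s2, model).dotbracket)
        self_score = forest_align_score(f1, f1)
        assert forest_align_score(f1, f2) < self_score


class TestMultipleStructureAlign:
    def _folds(self, model, seqs_dbs):
        from planac.folding import FoldResult
        from planac.io_formats import parse_dotbracket

        out = []
        for sid, seq, db in seqs_dbs:
            pairs = tuple(parse_dotbracket(db))
            out.append((Sequence(sid, seq),
                        FoldResult(pairs, 0.0, len(seq))))
        return out

    def test_identical_folds_ungapped(self, model):
        folds = self._folds(
            model,
            [(f"s{i}", "GGGAAACCC", "(((...)))") for i in range(4)],
        )
        y = multiple_structure_align(folds)
        aln = implied_sequence_alignment(y)
        assert aln.n_cols == 9
        assert all(row == "GGGAAACCC" for _, row in aln.rows)

    def test_two_equals_pairwise(self, model):
        folds = self._folds(
            model,
            [("a", "GGGAAACCC", "(((...)))"), ("b", "AGGAAACCU", "(((...)))")],
        )
        y2 = multiple_structure_align(folds)
        f1 = forest_from_structure(folds[0][0], "(((...)))")
        f2 = forest_from_structure(folds[1][0], "(((...)))")
        yp, _ = pairwise_forest_align(f1, f2)
        assert implied_sequence_alignment(y2).rows == \
            implied_sequence_alignment(yp).rows

    def test_rejects_single(self, model):
        with pytest.raises(ValueError):
            multiple_structure_align(self._folds(model, [("a", "ACGU", "....")]))

    def test_family_shared_shape_pair_columns(self, model, small_family):
        seqs, _, _ = small_family
        folds = [(s, mfe_fold(s, model)) for s in seqs]
        y = multiple_structure_align(folds)
        aln = implied_sequence_alignment(y)
        for i, s in enumerate(seqs):
            assert aln.degapped(i).residues == s.residues
        # consensus bracket columns are properly nested
        from planac.io_formats import parse_dotbracket

        parse_dotbracket(y.consensus_dotbracket())


class TestImpliedAlignment:
    def test_self_alignment(self, rng):
        seq = random_rna(rng, 10)
        db = random_structure(rng, 10)
        f = forest_from_structure(Sequence("x", seq), db)
        g = forest_from_structure(Sequence("y", seq), db)
        y, _ = pairwise_forest_align(f, g)
        aln = implied_sequence_alignment(y)
        assert aln.row(0) == aln.row(1) == seq

    def test_degapping_law_random(self, rng):
        for _ in range(10):
            n1, n2 = int(rng.integers(4, 14)), int(rng.integers(4, 14))
            s1 = Sequence("a", random_rna(rng, n1))
            s2 = Sequence("b", random_rna(rng, n2))
            f1 = forest_from_structure(s1, random_structure(rng, n1))
            f2 = forest_from_structure(s2, random_structure(rng, n2))
            y, _ = pairwise_forest_align(f1, f2)
            aln = implied_sequence_alignment(y)
            assert aln.degapped(0).residues == s1.residues
            assert aln.degapped(1).residues == s2.residues
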