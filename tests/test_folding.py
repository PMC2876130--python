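import math

import pytest

from oracles import brute_force_constrained, brute_force_mfe
from planac.folding import (
    EnergyModel,
    _DEFAULT_PAIR_ENERGIES,
    alifold,
    constrained_fold,
    mfe_fold,
    project_consensus,
    structure_energy,
)
from planac.io_formats import MultipleAlignment, Sequence

from conftest import random_rna


class TestEnergyModel:
    def test_defaults(self, model):
        assert model.pair_energy("G", "C") == -3.0
        assert model.pair_energy("A", "C") is None
        assert model.min_hairpin == 3

    def test_invalid(self):
        with pytest.raises(ValueError):
            EnergyModel(min_hairpin=2)
        with pytest.raises(ValueError):
            EnergyModel(stack=0.5)


class TestMfeFold:
    def test_hairpin(self, model):
        fr = mfe_fold(Sequence("x", "GGGAAACCC"), model)
        assert fr.dotbracket == "(((...)))"
        # three CG pairs, two of them stacked on the one below
        assert fr.energy == 3 * -3.0 + 2 * -1.0

    def test_no_canonical_pairs(self, model):
        fr = mfe_fold(Sequence("x", "AAAAAA"), model)
        assert fr.pairs == () and fr.energy == 0.0

    def test_too_short_for_hairpin(self, model):
        assert mfe_fold(Sequence("x", "ACG"), model).pairs == ()

    def test_matches_bruteforce(self, model, rng):
        for _ in range(100):
            seq = random_rna(rng, int(rng.integers(4, 13)))
            fr = mfe_fold(Sequence("x", seq), model)
            best_e, _ = brute_force_mfe(seq, _DEFAULT_PAIR_ENERGIES)
            assert fr.energy == pytest.approx(best_e), seq

    def test_rescoring_law(self, model, rng):
        for _ in range(20):
            s = Sequence("x", random_rna(rng, 30))
            fr = mfe_fold(s, model)
            assert structure_energy(s, fr.pairs, model) == pytest.approx(
                fr.energy, abs=1e-9
            )


class TestConstrainedFold:
    def test_empty_constraints_reduce_to_mfe(self, model):
        s = Sequence("x", "GGGAAACCCAAAGGGAAACCC")
        assert constrained_fold(s, (), model) == mfe_fold(s, model)

    def test_full_mfe_structure_idempotent(self, model):
        s = Sequence("x", "GGGAAACCCAAAGGGAAACCC")
        fr = mfe_fold(s, model)
        again = constrained_fold(s, fr.pairs, model)
        assert again.pairs == fr.pairs
        assert again.energy == pytest.approx(fr.energy)

    def test_single_outer_pair_bruteforce(self, model):
        seq = "GGGAAACCCAAAGGGAAACCC"
        s = Sequence("x", seq)
        constraint = [(0, 8)]
        fr = constrained_fold(s, constraint, model)
        assert set(constraint) <= set(fr.pairs)
        expected = brute_force_constrained(seq, constraint,
                                           _DEFAULT_PAIR_ENERGIES)
        assert fr.energy == pytest.approx(expected)
        assert fr.energy >= mfe_fold(s, model).energy - 1e-9
        assert fr.energy <= structure_energy(s, constraint, model) + 1e-9

    def test_superset_and_energy_laws(self, model, rng):
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(8, 15)))
            s = Sequence("x", seq)
            base = mfe_fold(s, model)
            if not base.pairs:
                continue
            constraint = base.pairs[:1]
            fr = constrained_fold(s, constraint, model)
            assert set(constraint) <= set(fr.pairs)
            assert fr.energy >= base.energy - 1e-9
            expected = brute_force_constrained(seq, constraint,
                                               _DEFAULT_PAIR_ENERGIES)
            assert fr.energy == pytest.approx(expected)

    def test_noncanonical_constraint_rejected(self, model):
        with pytest.raises(ValueError, match="non-canonical"):
            constrained_fold(Sequence("x", "AAAAAAAAA"), [(0, 8)], model)

    def test_crossing_constraints_rejected(self, model):
        s = Sequence("x", "GGGGAAAACCCCUUUU")
        with pytest.raises(ValueError, match="cross"):
            constrained_fold(s, [(0, 11), (2, 14)], model)


class TestAlifold:
    def test_identical_rows_equal_single_sequence_fold(self, model):
        seq = "GGGAAACCCAAAGGGAAACCC"
        aln = MultipleAlignment(tuple((f"s{i}", seq) for i in range(4)))
        cons = alifold(aln, model)
        fr = mfe_fold(Sequence("x", seq), model)
        assert cons.pairs == fr.pairs
        assert cons.energy == pytest.approx(fr.energy)
        assert all(c == 0.0 for c in cons.covariance.values())

    def test_shifted_gap_alignment_misses_inner_pair(self, model):
        # the motivating mis-alignment: both shifted gaps sit right of
        # the mismatched base, hiding the helix of the first row
        aln = MultipleAlignment(
            (("s1", "AAGGAAAACCAA"), ("s2", "AAC-AAAAG-AA"))
        )
        cons = alifold(aln, model)
        assert (3, 8) not in cons.pairs
        assert (2, 9) not in cons.pairs
        # the cross-supported pair is what survives
        assert (2, 8) in cons.pairs

    def test_compensatory_beats_pair_breaking(self, model):
        # helix column pair with a compensatory change in row 2 ...
        comp = MultipleAlignment(
            (("a", "GGGAAACCC"), ("b", "AGGAAACCU"))
        )
        # ... versus a substitution that breaks the pair
        broken = MultipleAlignment(
            (("a", "GGGAAACCC"), ("b", "AGGAAACCA"))
        )
        e_comp = alifold(comp, model)
        e_broken = alifold(broken, model)

        def pair_score(cons):
            return cons.energy

        assert (0, 8) in e_comp.pairs
        assert pair_score(e_comp) < pair_score(e_broken)

    def test_requires_two_rows(self, model):
        with pytest.raises(ValueError):
            alifold(MultipleAlignment((("a", "GGGAAACCC"),)), model)

    def test_energy_finite(self, model, small_family):
        _, ref_aln, _ = small_family
        cons = alifold(ref_aln, model)
        assert math.isfinite(cons.energy)


class TestProjectConsensus:
    def test_ungapped_row_identity(self, model):
        seq = "GGGAAACCC"
        aln = MultipleAlignment((("a", seq), ("b", seq)))
        cons = alifold(aln, model)
        assert project_consensus(cons, aln, 0, model) == cons.pairs

    def test_gap_drops_pair_and_reindexes(self, model):
        from planac.folding import ConsensusStructure

        cons = ConsensusStructure(((2, 9), (3, 8)), -6.0, 12)
        aln = MultipleAlignment(
            (("a", "AAGGAAAACCAA"), ("b", "AA-GAAAACCAA"))
        )
        # row b: gap under column 2 kills (2,9); (3,8) re-indexes to (2,7)
        assert project_consensus(cons, aln, 1, model) == ((2, 7),)

    def test_noncanonical_projected_pair_dropped(self, model):
        from planac.folding import ConsensusStructure

        cons = ConsensusStructure(((2, 9), (3, 8)), -6.0, 12)
        aln = MultipleAlignment(
            (("a", "AAGGAAAACCAA"), ("b", "AAAGAAAACCAA"))
        )
        # row b has A at column 2: A-C is non-canonical, pair dropped
        assert project_consensus(cons, aln, 1, model) == ((3, 8),)

    def test_projection_maps_back_into_consensus(self, model, small_family):
        seqs, ref_aln, _ = small_family
        cons = alifold(ref_aln, model)
        for i in range(ref_aln.n_rows):
            row = ref_aln.row(i)
            coord_to_col = [j for j, ch in enumerate(row) if ch != "-"]
            projected = project_consensus(cons, ref_aln, i, model)
            back = {(coord_to_col[a], coord_to_col[b]) for a, b in projected}
            assert back <= set(cons.pairs)
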