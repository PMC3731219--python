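"""Folding, structure arithmetic, and the exhaustive-enumeration oracle."""

import numpy as np
import pytest

from ribodesign import (
    DotBracketStructure,
    NucleotideSequence,
    CapabilityError,
    SequenceError,
    StructureError,
    cofold,
    enumerate_structures,
    evaluate_structure,
    fold,
    pair_probabilities,
)

from conftest import random_seq


def seq(residues, name="s"):
    return NucleotideSequence(name, residues)


class TestDotBracket:
    def test_parse_and_pair_map(self):
        s = DotBracketStructure("((....))")
        assert s.pair_map == ((0, 7), (1, 6))

    def test_multistrand_intermolecular_pairs(self):
        s = DotBracketStructure("(((&)))")
        assert s.pair_map == ((0, 5), (1, 4), (2, 3))
        assert s.strand_lengths == (3, 3)

    def test_unbalanced_raises(self):
        with pytest.raises(StructureError):
            DotBracketStructure("((..)")
        with pytest.raises(StructureError):
            DotBracketStructure("..)..")

    def test_hairpin_minimum_enforced_within_strand(self):
        with pytest.raises(StructureError):
            DotBracketStructure("(())")
        with pytest.raises(StructureError):
            DotBracketStructure("()()")

    def test_from_pairs_round_trip(self):
        s = DotBracketStructure("((....))..")
        rebuilt = DotBracketStructure.from_pairs([10], s.pair_map)
        assert rebuilt.symbols == s.symbols

    def test_invalid_symbol(self):
        with pytest.raises(StructureError):
            DotBracketStructure("..x..")


class TestSequence:
    def test_alphabet_enforced(self):
        with pytest.raises(SequenceError):
            NucleotideSequence("x", "ACGT")  # DNA not allowed

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            NucleotideSequence("x", "")

    def test_mask_length_checked(self):
        with pytest.raises(SequenceError):
            NucleotideSequence("x", "ACGU", (True,))


class TestFold:
    @pytest.mark.parametrize(
        "residues,structure,energy",
        [
            ("GGGAAAACCC", "(((....)))", -9.0),
            ("AAAAA", ".....", 0.0),
            ("ACGU", "....", 0.0),  # hairpin minimum forbids any pair
        ],
    )
    def test_known_folds(self, model, residues, structure, energy):
        result = fold(seq(residues), model)
        assert result.structure.symbols == structure
        assert result.free_energy == pytest.approx(energy)

    def test_energy_matches_structure_evaluation(self, model, rng):
        for _ in range(25):
            s = random_seq(rng, int(rng.integers(5, 16)))
            r = fold(s, model)
            assert r.free_energy == pytest.approx(
                evaluate_structure(s, r.structure, model)
            )

    def test_mfe_equals_enumeration_minimum(self, model, rng):
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(4, 11)))
            best = min(e for _, e in enumerate_structures(s, model))
            assert fold(s, model).free_energy == pytest.approx(best)

    def test_removing_a_pair_never_beats_mfe(self, model, rng):
        for _ in range(10):
            s = random_seq(rng, 12)
            r = fold(s, model)
            for drop in range(len(r.structure.pair_map)):
                pairs = [p for i, p in enumerate(r.structure.pair_map)
                         if i != drop]
                sub = DotBracketStructure.from_pairs([len(s)], pairs)
                assert evaluate_structure(s, sub, model) >= r.free_energy

    def test_deterministic(self, model, rng):
        s = random_seq(rng, 14)
        a = fold(s, model)
        b = fold(s, model)
        assert a.structure.symbols == b.structure.symbols
        assert a.free_energy == b.free_energy


class TestCofold:
    def test_full_duplex(self, model):
        r = cofold([seq("GGGG", "a"), seq("CCCC", "b")], model)
        assert r.free_energy == pytest.approx(-12.0)
        inter = [p for p in r.structure.pair_map if p[1] >= 4 > p[0]]
        assert len(inter) == 4

    def test_non_interacting(self, model):
        r = cofold([seq("AAAA", "a"), seq("AAAA", "b")], model)
        assert r.free_energy == 0.0
        assert r.structure.pair_map == ()

    def test_inert_partner_leaves_fold_unchanged(self, model):
        hairpin = seq("GGGAAAACCC")
        alone = fold(hairpin, model)
        with_a = cofold([hairpin, seq("AAAA", "b")], model)
        assert with_a.free_energy == pytest.approx(alone.free_energy)

    def test_three_strands_supported_four_rejected(self, model):
        r = cofold([seq("GGG", "a"), seq("AAA", "b"), seq("CCC", "c")], model)
        assert r.free_energy <= -9.0 + 1e-9
        with pytest.raises(CapabilityError):
            cofold([seq("A", str(i)) for i in range(4)], model)

    def test_intermolecular_exempt_from_hairpin_minimum(self, model):
        # a 2-nt strand can still pair its partner
        r = cofold([seq("GG", "a"), seq("CC", "b")], model)
        assert r.free_energy == pytest.approx(-6.0)


class TestEvaluateStructure:
    def test_additive_sum(self, model):
        s = seq("GGGAAAACCC")
        assert evaluate_structure(
            s, DotBracketStructure("(((....)))"), model
        ) == pytest.approx(-9.0)

    def test_all_dots_is_zero(self, model, rng):
        s = random_seq(rng, 9)
        assert evaluate_structure(
            s, DotBracketStructure("." * 9), model
        ) == 0.0

    def test_non_complementary_pair_rejected(self, model):
        s = seq("GGGAAAAGGG")
        with pytest.raises(StructureError):
            evaluate_structure(s, DotBracketStructure("(((....)))"), model)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(StructureError):
            evaluate_structure(seq("ACGU"), DotBracketStructure("....."), model)


class TestPairProbabilities:
    def test_no_intramolecular_pairs_gives_zero_matrix(self, model):
        P = pair_probabilities(seq("GGGG"), model, rt=0.61)
        assert np.all(P == 0)

    def test_entries_in_unit_interval_and_symmetric(self, model, rng):
        P = pair_probabilities(
            [random_seq(rng, 5, "a"), random_seq(rng, 5, "b")], model, rt=0.61
        )
        assert np.all(P >= 0) and np.all(P <= 1)
        assert np.allclose(P, P.T)

    def test_low_temperature_concentrates_on_mfe(self, model):
        a, b = seq("GGGG", "a"), seq("CCCC", "b")
        P = pair_probabilities([a, b], model, rt=0.01)
        mfe = cofold([a, b], model)
        for i, j in mfe.structure.pair_map:
            assert P[i, j] == pytest.approx(1.0, abs=1e-6)

    def test_size_limit(self, model, rng):
        with pytest.raises(CapabilityError):
            pair_probabilities(random_seq(rng, 40), model, rt=0.61)
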