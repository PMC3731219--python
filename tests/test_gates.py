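"""Gate builders, constraint handling, and spec validation."""

import pytest

from ribodesign import (
    SpecError,
    constrain_gate,
    make_and_gate,
    make_not_gate,
    make_yes_gate,
    validate_spec,
)
from ribodesign.gates import (
    GateSpec,
    SHINE_DALGARNO,
    default_hairpin,
    gate_from_dict,
    gate_to_dict,
)


def kin_terms(gate):
    return [t for t in gate.terms if t.kind == "kin"]


def str_terms(gate):
    return [t for t in gate.terms if t.kind == "str"]


class TestNotGate:
    def test_default_term_counts(self):
        gate = make_not_gate()
        assert len(gate.entries) == 2
        assert len(kin_terms(gate)) == 1
        assert kin_terms(gate)[0].sense == "occur"
        assert len(str_terms(gate)) == 2

    def test_sd_motif_spacing(self):
        gate = make_not_gate(utr_len=30)
        mrna = gate.species_by_name()["mRNA"]
        sd = next(m for m in mrna.motifs if m.sequence == SHINE_DALGARNO)
        aug = next(m for m in mrna.motifs if m.sequence == "AUG")
        assert aug.start - sd.end == 8
        assert aug.end == 30

    def test_srna_too_short_for_sd(self):
        with pytest.raises(SpecError):
            make_not_gate(srna_len=5)

    @pytest.mark.parametrize("stem", [4, 5, 6])
    def test_alternative_srna_hairpins_accepted(self, stem):
        gate = make_not_gate(srna_target_structure=default_hairpin(20, stem))
        validate_spec(gate)

    def test_builder_output_validates(self):
        validate_spec(make_not_gate())


class TestYesGate:
    def test_cis_repressed_utr_mask(self):
        gate = make_yes_gate()
        alone = next(t for t in str_terms(gate) if t.a == ("mRNA",))
        rbs = gate.meta["rbs"]
        assert all(alone.target[p] == "|" for p in rbs)
        # the UTR target structure itself pairs the SD
        mrna = gate.species_by_name()["mRNA"]
        assert all(mrna.target_structure[p] == ")" for p in rbs)

    def test_not_cis_variant_flips_masks(self):
        gate = make_yes_gate(variant="NOT_cis")
        alone = next(t for t in str_terms(gate) if t.a == ("mRNA",))
        cx = next(t for t in str_terms(gate) if len(t.a) == 2)
        rbs = gate.meta["rbs"]
        assert all(alone.target[p] == "." for p in rbs)
        srna_len = gate.species_by_name()["sRNA"].length
        assert all(cx.target[srna_len + p] == "|" for p in rbs)

    def test_antiterm_variant_targets_terminator_stem(self):
        gate = make_yes_gate(variant="YES_antiterm")
        mrna = gate.species_by_name()["mRNA"]
        assert any(m.sequence == "UUUUUU" for m in mrna.motifs)
        stem = gate.meta["terminator_stem"]
        alone = next(t for t in str_terms(gate) if t.a == ("mRNA",))
        assert all(alone.target[p] == "|" for p in stem)
        cx = next(t for t in str_terms(gate) if len(t.a) == 2)
        srna_len = gate.species_by_name()["sRNA"].length
        assert all(cx.target[srna_len + p] == "." for p in stem)

    def test_builders_validate(self):
        for variant in ("YES", "NOT_cis", "YES_antiterm"):
            validate_spec(make_yes_gate(variant=variant))


class TestAndGate:
    def test_four_truth_table_entries(self):
        gate = make_and_gate()
        assert len(gate.entries) == 4
        inputs = {frozenset(e.inputs_present) for e in gate.entries}
        assert frozenset() in inputs
        assert frozenset({"sRNA1", "sRNA2"}) in inputs

    def test_single_srnas_carry_avoid_terms(self):
        gate = make_and_gate()
        avoid = [t for t in kin_terms(gate) if t.sense == "avoid"]
        assert {t.a[0] for t in avoid} == {"sRNA1", "sRNA2"}

    def test_dimer_occurs_and_releases_rbs(self):
        gate = make_and_gate()
        occur = [t for t in kin_terms(gate) if t.sense == "occur"]
        assert (("sRNA1",), ("sRNA2",)) in [(t.a, t.b) for t in occur]
        triple = next(t for t in str_terms(gate) if len(t.a) == 3)
        assert "." in triple.target


class TestConstrainGate:
    def test_fixing_clears_designability(self):
        gate = make_not_gate()
        srna = gate.species_by_name()["sRNA"]
        # must satisfy the sRNA's hairpin target: stem of 6 + loop of 8
        fixed = "GCAUGC" + "ACGUACGA" + "GCAUGC"
        assert len(fixed) == srna.length
        new = constrain_gate(gate, {"sRNA": fixed})
        sp = new.species_by_name()["sRNA"]
        assert sp.fixed_sequence is not None
        assert not any(sp.base_mask())

    def test_fixed_sequence_must_respect_motifs(self):
        gate = make_not_gate(utr_len=30)
        with pytest.raises(SpecError):
            constrain_gate(gate, {"mRNA": "A" * 30})

    def test_unknown_species_rejected(self):
        with pytest.raises(SpecError):
            constrain_gate(make_not_gate(), {"ghost": "ACGU"})


class TestValidateSpec:
    def test_missing_truth_table_entry(self):
        gate = make_not_gate()
        broken = GateSpec(gate.gate_type, gate.species, gate.entries[:1],
                          gate.reactions, gate.terms, gate.meta)
        with pytest.raises(SpecError):
            validate_spec(broken)

    def test_forced_non_complementary_pair(self):
        # target structure pairs two positions both forced by a fixed sequence
        from ribodesign.gates import SpeciesSpec

        gate = make_not_gate(srna_len=20)
        bad = SpeciesSpec(
            name="sRNA", role="sRNA", length=20,
            target_structure="((" + "." * 16 + "))",
            fixed_sequence="GG" + "ACAC" * 4 + "GG",  # G-G cannot pair
        )
        broken = GateSpec(gate.gate_type, [bad, gate.species[1]],
                          gate.entries, gate.reactions, gate.terms, gate.meta)
        with pytest.raises(SpecError, match="non-complementary"):
            validate_spec(broken)

    def test_kin_term_per_reaction_enforced(self):
        gate = make_not_gate()
        broken = GateSpec(gate.gate_type, gate.species, gate.entries,
                          gate.reactions + [(("sRNA",), ("mRNA",), "avoid")],
                          gate.terms, gate.meta)
        with pytest.raises(SpecError):
            validate_spec(broken)


class TestSerialization:
    @pytest.mark.parametrize("builder", [make_not_gate, make_yes_gate,
                                         make_and_gate])
    def test_dict_round_trip(self, builder):
        gate = builder()
        data = gate_to_dict(gate)
        back = gate_from_dict(data)
        assert gate_to_dict(back) == data

    def test_unknown_keys_rejected(self):
        data = gate_to_dict(make_not_gate())
        data["surprise"] = 1
        with pytest.raises(SpecError):
            gate_from_dict(data)
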