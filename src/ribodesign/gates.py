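"""Declarative specifications of sRNA logic devices.

A gate is a set of RNA species (trans-acting sRNAs and a 5' UTR of the
target mRNA), a truth table mapping each input combination to a structural
requirement (RBS accessible/blocked, terminator formed/disrupted), the
reactions that must or must not occur, and the objective terms those
choices induce.  Builders produce the devices:

* NOT (direct): the sRNA pairs the Shine-Dalgarno (SD) region of an
  otherwise open UTR, blocking ribosome docking.
* YES: the UTR is cis-repressed (an anti-SD hairpin sequesters the SD); the
  sRNA releases it.
* NOT (cis): the sRNA drives the UTR into an SD-paired conformation.
* YES (anti-termination): the UTR carries an intrinsic terminator hairpin
  plus poly(U) tail upstream of the SD; the sRNA disrupts the stem.
* AND: two sRNAs are inert alone, dimerize, and the dimer opens the UTR.

Constrained (re)design — fixing one species' sequence and redesigning the
others — turns these primitives into coupled YES/NOT and OR devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

from .energy_model import DotBracketStructure, RNA_ALPHABET, is_wc_pair
from .errors import SpecError
from .objective import ObjectiveTerm

SHINE_DALGARNO = "AGGAGA"
START_CODON = "AUG"
#: SD is placed this many nt upstream of the start codon
SD_AUG_SPACING = 8
POLY_U_TAIL = "UUUUUU"

GateType = Literal[
    "NOT_direct", "YES", "NOT_cis", "YES_antiterm", "AND",
    "coupled_YES_NOT", "OR_extend",
]


@dataclass(frozen=True)
class Motif:
    """A fixed subsequence at a fixed 0-based position."""

    sequence: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    role: Literal["sRNA", "mRNA_5UTR"]
    length: int
    target_structure: str
    motifs: tuple[Motif, ...] = ()
    fixed_sequence: str | None = None
    designable_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        DotBracketStructure(self.target_structure)  # validates
        if len(self.target_structure) != self.length:
            raise SpecError(
                f"{self.name}: target structure length != species length"
            )
        taken: set[int] = set()
        for m in self.motifs:
            if m.start < 0 or m.end > self.length:
                raise SpecError(f"{self.name}: motif {m.sequence} out of range")
            span = set(range(m.start, m.end))
            if taken & span:
                raise SpecError(f"{self.name}: overlapping motifs")
            taken |= span
        if self.fixed_sequence is not None:
            if len(self.fixed_sequence) != self.length:
                raise SpecError(f"{self.name}: fixed sequence length mismatch")
            for m in self.motifs:
                if self.fixed_sequence[m.start : m.end] != m.sequence:
                    raise SpecError(
                        f"{self.name}: fixed sequence violates motif "
                        f"{m.sequence} at {m.start + 1}"
                    )
        if self.designable_mask is not None:
            if len(self.designable_mask) != self.length:
                raise SpecError(f"{self.name}: designable mask length mismatch")

    def base_mask(self) -> tuple[bool, ...]:
        """Designable mask: False on motifs and on fully fixed species."""
        if self.designable_mask is not None:
            return self.designable_mask
        if self.fixed_sequence is not None:
            return tuple(False for _ in range(self.length))
        mask = [True] * self.length
        for m in self.motifs:
            for p in range(m.start, m.end):
                mask[p] = False
        return tuple(mask)

    def target_pairs(self) -> tuple[tuple[int, int], ...]:
        return DotBracketStructure(self.target_structure).pair_map


@dataclass(frozen=True)
class TruthTableEntry:
    inputs_present: frozenset[str]
    required_output: Literal[
        "RBS_accessible", "RBS_blocked", "terminator_formed",
        "terminator_disrupted",
    ]


@dataclass
class GateSpec:
    gate_type: GateType
    species: list[SpeciesSpec]
    entries: list[TruthTableEntry]
    reactions: list[tuple[tuple[str, ...], tuple[str, ...], str]]
    terms: list[ObjectiveTerm] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def species_by_name(self) -> dict[str, SpeciesSpec]:
        return {sp.name: sp for sp in self.species}


def _mask_string(length: int, positions: Iterable[int], char: str) -> str:
    chars = ["*"] * length
    for p in positions:
        chars[p] = char
    return "".join(chars)


def _complex_mask(
    lengths: Iterable[int], species_index: int, positions: Iterable[int], char: str
) -> str:
    """Mask over a multi-strand complex targeting one strand's positions."""
    parts = []
    for s, ln in enumerate(lengths):
        if s == species_index:
            parts.append(_mask_string(ln, positions, char))
        else:
            parts.append("*" * ln)
    return "".join(parts)


def default_hairpin(length: int, stem: int = 6) -> str:
    """A centred hairpin target: ``stem`` pairs around an open loop."""
    loop = length - 2 * stem
    if loop < DotBracketStructure.MIN_HAIRPIN_LOOP + 1:
        raise SpecError(f"length {length} too short for a stem of {stem}")
    return "(" * stem + "." * loop + ")" * stem


def _utr_layout(utr_len: int) -> dict[str, int]:
    """Positions of SD, spacer, and AUG at the 3' end of the UTR."""
    aug_start = utr_len - len(START_CODON)
    sd_start = aug_start - SD_AUG_SPACING - len(SHINE_DALGARNO)
    if sd_start < 0:
        raise SpecError(
            f"UTR of {utr_len} nt cannot host SD + {SD_AUG_SPACING} nt spacer + AUG"
        )
    return {"sd_start": sd_start, "aug_start": aug_start}


def _rbs_positions(layout: Mapping[str, int]) -> list[int]:
    return list(range(layout["sd_start"], layout["sd_start"] + len(SHINE_DALGARNO)))


def make_not_gate(
    utr_len: int = 30,
    srna_len: int = 20,
    srna_target_structure: str | None = None,
) -> GateSpec:
    """NOT gate: the sRNA binds the SD region and blocks translation.

    Without input the UTR is open (RBS accessible); with the sRNA present
    the sRNA:mRNA complex must hold the RBS paired.
    """
    if srna_len < len(SHINE_DALGARNO):
        raise SpecError("sRNA shorter than the SD sequence cannot cover it")
    layout = _utr_layout(utr_len)
    rbs = _rbs_positions(layout)
    mrna = SpeciesSpec(
        name="mRNA",
        role="mRNA_5UTR",
        length=utr_len,
        target_structure="." * utr_len,
        motifs=(
            Motif(SHINE_DALGARNO, layout["sd_start"]),
            Motif(START_CODON, layout["aug_start"]),
        ),
    )
    srna = SpeciesSpec(
        name="sRNA",
        role="sRNA",
        length=srna_len,
        target_structure=srna_target_structure or default_hairpin(srna_len),
    )
    entries = [
        TruthTableEntry(frozenset(), "RBS_accessible"),
        TruthTableEntry(frozenset({"sRNA"}), "RBS_blocked"),
    ]
    reactions = [(("sRNA",), ("mRNA",), "occur")]
    terms = [
        ObjectiveTerm("kin", ("sRNA",), ("mRNA",), sense="occur",
                      label="sRNA:mRNA must occur"),
        ObjectiveTerm("str", ("mRNA",),
                      target=_mask_string(utr_len, rbs, "."),
                      label="mRNA alone: RBS accessible"),
        ObjectiveTerm("str", ("sRNA", "mRNA"),
                      target=_complex_mask([srna_len, utr_len], 1, rbs, "|"),
                      label="complex: RBS blocked"),
    ]
    gate = GateSpec("NOT_direct", [srna, mrna], entries, reactions, terms,
                    meta={"rbs": rbs, "utr_layout": dict(layout)})
    validate_spec(gate)
    return gate


def _cis_repressed_utr(utr_len: int) -> tuple[str, dict[str, int]]:
    """UTR target structure whose anti-SD stem sequesters the SD."""
    layout = _utr_layout(utr_len)
    sd = layout["sd_start"]
    n = len(SHINE_DALGARNO)
    loop = DotBracketStructure.MIN_HAIRPIN_LOOP
    anti_start = sd - loop - n
    if anti_start < 0:
        raise SpecError(f"UTR of {utr_len} nt too short for cis-repression")
    chars = ["."] * utr_len
    for t in range(n):
        chars[anti_start + t] = "("
        chars[sd + t] = ")"
    layout = dict(layout, anti_sd_start=anti_start)
    return "".join(chars), layout


def make_yes_gate(
    utr_len: int | None = None,
    srna_len: int = 20,
    utr_target_structure: str | None = None,
    srna_target_structure: str | None = None,
    variant: Literal["YES", "NOT_cis", "YES_antiterm"] = "YES",
) -> GateSpec:
    """YES gate and its variants, built around a structured 5' UTR.

    YES: UTR alone is cis-repressed (SD paired); sRNA releases it.
    NOT_cis: UTR alone is open; the sRNA:mRNA complex pairs the SD.
    YES_antiterm: UTR alone forms a terminator hairpin + poly(U); the sRNA
    disrupts the stem so transcription reads through.
    """
    if variant == "YES_antiterm":
        return _make_antiterm_gate(utr_len or 44, srna_len,
                                   srna_target_structure)
    if utr_len is None:
        utr_len = 32
    layout: dict[str, int]
    if utr_target_structure is None:
        if variant == "YES":
            utr_target_structure, layout = _cis_repressed_utr(utr_len)
        else:  # NOT_cis: open UTR alone
            layout = _utr_layout(utr_len)
            utr_target_structure = "." * utr_len
    else:
        layout = _utr_layout(utr_len)
    rbs = _rbs_positions(layout)
    mrna = SpeciesSpec(
        name="mRNA", role="mRNA_5UTR", length=utr_len,
        target_structure=utr_target_structure,
        motifs=(
            Motif(SHINE_DALGARNO, layout["sd_start"]),
            Motif(START_CODON, layout["aug_start"]),
        ),
    )
    srna = SpeciesSpec(
        name="sRNA", role="sRNA", length=srna_len,
        target_structure=srna_target_structure or default_hairpin(srna_len, stem=5),
    )
    if variant == "YES":
        alone_char, complex_char = "|", "."
        outputs = ("RBS_blocked", "RBS_accessible")
    else:
        alone_char, complex_char = ".", "|"
        outputs = ("RBS_accessible", "RBS_blocked")
    entries = [
        TruthTableEntry(frozenset(), outputs[0]),
        TruthTableEntry(frozenset({"sRNA"}), outputs[1]),
    ]
    reactions = [(("sRNA",), ("mRNA",), "occur")]
    terms = [
        ObjectiveTerm("kin", ("sRNA",), ("mRNA",), sense="occur",
                      label="sRNA:mRNA must occur"),
        ObjectiveTerm("str", ("mRNA",),
                      target=_mask_string(utr_len, rbs, alone_char),
                      label=f"mRNA alone: {outputs[0]}"),
        ObjectiveTerm("str", ("sRNA", "mRNA"),
                      target=_complex_mask([srna_len, utr_len], 1, rbs,
                                           complex_char),
                      label=f"complex: {outputs[1]}"),
    ]
    gate = GateSpec(variant if variant != "YES" else "YES",
                    [srna, mrna], entries, reactions, terms,
                    meta={"rbs": rbs, "utr_layout": dict(layout)})
    validate_spec(gate)
    return gate


def _make_antiterm_gate(
    utr_len: int = 42, srna_len: int = 20,
    srna_target_structure: str | None = None,
    stem: int = 6, term_loop: int = 4,
) -> GateSpec:
    layout = _utr_layout(utr_len)
    hp_len = 2 * stem + term_loop
    polyu_start = hp_len
    if polyu_start + len(POLY_U_TAIL) > layout["sd_start"]:
        raise SpecError(
            f"UTR of {utr_len} nt too short for terminator + poly(U) + SD"
        )
    chars = ["."] * utr_len
    for t in range(stem):
        chars[t] = "("
        chars[hp_len - 1 - t] = ")"
    target = "".join(chars)
    stem_positions = list(range(stem)) + list(range(stem + term_loop, hp_len))
    mrna = SpeciesSpec(
        name="mRNA", role="mRNA_5UTR", length=utr_len, target_structure=target,
        motifs=(
            Motif(POLY_U_TAIL, polyu_start),
            Motif(SHINE_DALGARNO, layout["sd_start"]),
            Motif(START_CODON, layout["aug_start"]),
        ),
    )
    srna = SpeciesSpec(
        name="sRNA", role="sRNA", length=srna_len,
        target_structure=srna_target_structure or default_hairpin(srna_len, stem=5),
    )
    entries = [
        TruthTableEntry(frozenset(), "terminator_formed"),
        TruthTableEntry(frozenset({"sRNA"}), "terminator_disrupted"),
    ]
    reactions = [(("sRNA",), ("mRNA",), "occur")]
    terms = [
        ObjectiveTerm("kin", ("sRNA",), ("mRNA",), sense="occur",
                      label="sRNA:mRNA must occur"),
        ObjectiveTerm("str", ("mRNA",),
                      target=_mask_string(utr_len, stem_positions, "|"),
                      label="mRNA alone: terminator formed"),
        ObjectiveTerm("str", ("sRNA", "mRNA"),
                      target=_complex_mask([srna_len, utr_len], 1,
                                           stem_positions, "."),
                      label="complex: terminator disrupted"),
    ]
    gate = GateSpec("YES_antiterm", [srna, mrna], entries, reactions, terms,
                    meta={"rbs": _rbs_positions(layout),
                          "terminator_stem": stem_positions,
                          "utr_layout": dict(layout)})
    validate_spec(gate)
    return gate


def make_and_gate(
    utr_len: int = 32, srna_len: int = 16,
    srna1_target: str | None = None, srna2_target: str | None = None,
) -> GateSpec:
    """AND gate: two sRNAs dimerize; only the dimer releases the RBS."""
    utr_target, layout = _cis_repressed_utr(utr_len)
    rbs = _rbs_positions(layout)
    mrna = SpeciesSpec(
        name="mRNA", role="mRNA_5UTR", length=utr_len,
        target_structure=utr_target,
        motifs=(
            Motif(SHINE_DALGARNO, layout["sd_start"]),
            Motif(START_CODON, layout["aug_start"]),
        ),
    )
    s1 = SpeciesSpec("sRNA1", "sRNA", srna_len,
                     srna1_target or default_hairpin(srna_len, stem=4))
    s2 = SpeciesSpec("sRNA2", "sRNA", srna_len,
                     srna2_target or default_hairpin(srna_len, stem=4))
    entries = [
        TruthTableEntry(frozenset(), "RBS_blocked"),
        TruthTableEntry(frozenset({"sRNA1"}), "RBS_blocked"),
        TruthTableEntry(frozenset({"sRNA2"}), "RBS_blocked"),
        TruthTableEntry(frozenset({"sRNA1", "sRNA2"}), "RBS_accessible"),
    ]
    reactions = [
        (("sRNA1",), ("mRNA",), "avoid"),
        (("sRNA2",), ("mRNA",), "avoid"),
        (("sRNA1",), ("sRNA2",), "occur"),
        (("sRNA1", "sRNA2"), ("mRNA",), "occur"),
    ]
    lengths3 = [srna_len, srna_len, utr_len]
    terms = [
        ObjectiveTerm("kin", ("sRNA1",), ("mRNA",), sense="avoid",
                      label="sRNA1 alone must not act"),
        ObjectiveTerm("kin", ("sRNA2",), ("mRNA",), sense="avoid",
                      label="sRNA2 alone must not act"),
        ObjectiveTerm("kin", ("sRNA1",), ("sRNA2",), sense="occur",
                      label="dimer must form"),
        ObjectiveTerm("kin", ("sRNA1", "sRNA2"), ("mRNA",), sense="occur",
                      label="dimer:mRNA must occur"),
        ObjectiveTerm("str", ("mRNA",),
                      target=_mask_string(utr_len, rbs, "|"),
                      label="mRNA alone: RBS blocked"),
        ObjectiveTerm("str", ("sRNA1", "mRNA"),
                      target=_complex_mask([srna_len, utr_len], 1, rbs, "|"),
                      label="sRNA1:mRNA: RBS stays blocked"),
        ObjectiveTerm("str", ("sRNA2", "mRNA"),
                      target=_complex_mask([srna_len, utr_len], 1, rbs, "|"),
                      label="sRNA2:mRNA: RBS stays blocked"),
        ObjectiveTerm("str", ("sRNA1", "sRNA2", "mRNA"),
                      target=_complex_mask(lengths3, 2, rbs, "."),
                      label="triple complex: RBS released"),
    ]
    gate = GateSpec("AND", [s1, s2, mrna], entries, reactions, terms,
                    meta={"rbs": rbs, "utr_layout": dict(layout)})
    validate_spec(gate)
    return gate


def constrain_gate(
    base: GateSpec, fixed_species: Mapping[str, str], gate_type: GateType | None = None
) -> GateSpec:
    """Freeze the named species' sequences; everything else stays designable.

    Serial constrained design builds the combinatorial devices: fix the
    sRNA of a NOT gate and redesign the UTR for activation (coupled
    YES/NOT), or fix a designed UTR and add a second activating sRNA (OR).
    """
    by_name = base.species_by_name()
    new_species = []
    for sp in base.species:
        if sp.name in fixed_species:
            seq = fixed_species[sp.name]
            if set(seq) - set(RNA_ALPHABET):
                raise SpecError(f"{sp.name}: fixed sequence is not RNA")
            sp = replace(sp, fixed_sequence=seq, designable_mask=None)
        new_species.append(sp)
    unknown = set(fixed_species) - set(by_name)
    if unknown:
        raise SpecError(f"unknown species fixed: {sorted(unknown)}")
    gate = GateSpec(
        gate_type or base.gate_type, new_species, list(base.entries),
        list(base.reactions), list(base.terms), dict(base.meta),
    )
    validate_spec(gate)
    return gate


def validate_spec(gate: GateSpec) -> None:
    """Raise SpecError when the gate cannot be realized.

    Checks truth-table completeness, motif/structure compatibility (a
    target pair between two motif-forced bases must be Watson-Crick), and
    that every term references known species.
    """
    by_name = gate.species_by_name()
    inputs = sorted(sp.name for sp in gate.species if sp.role == "sRNA")
    want = {frozenset(c)
            for m in range(2 ** len(inputs))
            for c in [{inputs[i] for i in range(len(inputs)) if m >> i & 1}]}
    have = {e.inputs_present for e in gate.entries}
    if have != want:
        raise SpecError(
            f"truth table incomplete: have {sorted(map(sorted, have))}, "
            f"need one entry per subset of {inputs}"
        )
    for sp in gate.species:
        forced: dict[int, str] = {}
        for m in sp.motifs:
            for t, b in enumerate(m.sequence):
                forced[m.start + t] = b
        if sp.fixed_sequence is not None:
            forced.update(enumerate(sp.fixed_sequence))
        for i, j in sp.target_pairs():
            if i in forced and j in forced and not is_wc_pair(forced[i], forced[j]):
                raise SpecError(
                    f"{sp.name}: target pair ({i + 1},{j + 1}) forces "
                    f"non-complementary bases {forced[i]}-{forced[j]}"
                )
    for term in gate.terms:
        for name in term.a + term.b:
            if name not in by_name:
                raise SpecError(f"term references unknown species {name!r}")
        if term.kind == "str":
            ln = sum(by_name[n].length for n in term.a)
            if len(term.target.replace("&", "")) != ln:
                raise SpecError(
                    f"str target length mismatch for {term.a} "
                    f"({len(term.target)} vs {ln})"
                )
    n_kin = sum(1 for t in gate.terms if t.kind == "kin")
    if n_kin != len(gate.reactions):
        raise SpecError("one kin term required per reaction")


# ---------------------------------------------------------------------------
# serialization (round-trips losslessly through YAML-friendly dicts)

def gate_to_dict(gate: GateSpec) -> dict:
    return {
        "gate_type": gate.gate_type,
        "species": [
            {
                "name": sp.name,
                "role": sp.role,
                "length": sp.length,
                "target_structure": sp.target_structure,
                "motifs": [{"sequence": m.sequence, "start": m.start}
                           for m in sp.motifs],
                "fixed_sequence": sp.fixed_sequence,
                "designable_mask": (
                    list(sp.designable_mask) if sp.designable_mask else None
                ),
            }
            for sp in gate.species
        ],
        "entries": [
            {"inputs_present": sorted(e.inputs_present),
             "required_output": e.required_output}
            for e in gate.entries
        ],
        "reactions": [[list(a), list(b), sense]
                      for a, b, sense in gate.reactions],
        "terms": [
            {"kind": t.kind, "a": list(t.a), "b": list(t.b),
             "sense": t.sense, "target": t.target, "weight": t.weight,
             "label": t.label}
            for t in gate.terms
        ],
        "meta": gate.meta,
    }


def gate_from_dict(data: Mapping) -> GateSpec:
    known = {"gate_type", "species", "entries", "reactions", "terms", "meta"}
    unknown = set(data) - known
    if unknown:
        raise SpecError(f"unknown gate fields: {sorted(unknown)}")
    try:
        species = [
            SpeciesSpec(
                name=d["name"], role=d["role"], length=d["length"],
                target_structure=d["target_structure"],
                motifs=tuple(Motif(m["sequence"], m["start"])
                             for m in d.get("motifs", [])),
                fixed_sequence=d.get("fixed_sequence"),
                designable_mask=(tuple(d["designable_mask"])
                                 if d.get("designable_mask") else None),
            )
            for d in data["species"]
        ]
        entries = [
            TruthTableEntry(frozenset(e["inputs_present"]),
                            e["required_output"])
            for e in data["entries"]
        ]
        reactions = [(tuple(a), tuple(b), sense)
                     for a, b, sense in data["reactions"]]
        terms = [
            ObjectiveTerm(
                kind=t["kind"], a=tuple(t["a"]), b=tuple(t.get("b", ())),
                sense=t.get("sense"), target=t.get("target"),
                weight=t.get("weight", 1.0), label=t.get("label", ""),
            )
            for t in data["terms"]
        ]
    except KeyError as exc:
        raise SpecError(f"missing gate field: {exc}") from None
    gate = GateSpec(data["gate_type"], species, entries, reactions, terms,
                    dict(data.get("meta", {})))
    validate_spec(gate)
    return gate
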