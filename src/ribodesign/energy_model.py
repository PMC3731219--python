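"""Sequences, dot-bracket structures, and the reference energy model.

The reference model is deliberately minimal: every base pair contributes a
fixed negative energy (GC, AU, and optionally GU wobble), structures are
pseudoknot-free, and intramolecular pairs must close a hairpin loop of at
least three unpaired positions.  Minimality makes the minimum-free-energy
(MFE) prediction exhaustively verifiable at toy sizes, which is what the
test oracles rely on.  Realistic nearest-neighbour thermodynamics are
available through the :mod:`ribodesign.vienna` adapter, which satisfies the
same folding interface.

Coordinates are 0-based half-open internally; reports and file formats use
1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _dp
from .errors import CapabilityError, ParameterError, SequenceError, StructureError

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
WC_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "U"), ("U", "G")}


def complement(base: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    try:
        return WC_COMPLEMENT[base]
    except KeyError:
        raise SequenceError(f"not an RNA base: {base!r}") from None


def reverse_complement(residues: str) -> str:
    """Strict Watson-Crick reverse complement of an RNA string."""
    return "".join(complement(b) for b in reversed(residues))


def is_wc_pair(a: str, b: str) -> bool:
    return WC_COMPLEMENT.get(a) == b


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA string over {A,C,G,U} with a per-position designable mask.

    ``designable_mask[i]`` is True when position ``i`` may be mutated by the
    optimizer; fixed motifs (e.g. the Shine-Dalgarno sequence) and fully
    constrained species carry False entries.
    """

    name: str
    residues: str
    designable_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.name}: empty sequence")
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad:
            raise SequenceError(
                f"{self.name}: invalid residues {sorted(bad)} (alphabet is ACGU)"
            )
        if self.designable_mask is None:
            object.__setattr__(
                self, "designable_mask", tuple(True for _ in self.residues)
            )
        elif len(self.designable_mask) != len(self.residues):
            raise SequenceError(
                f"{self.name}: designable mask length {len(self.designable_mask)} "
                f"!= sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "NucleotideSequence":
        return replace(self, residues=residues)


@dataclass(frozen=True)
class DotBracketStructure:
    """Pseudoknot-free pairing of one or more strands.

    ``symbols`` is a Vienna-style dot-bracket string where ``&`` separates
    strands.  ``pair_map`` holds 0-based residue indices over the
    concatenation of all strands (separator excluded).  Intramolecular pairs
    must enclose at least :data:`MIN_HAIRPIN_LOOP` unpaired positions;
    intermolecular pairs are exempt.
    """

    MIN_HAIRPIN_LOOP = 3

    symbols: str
    pair_map: tuple[tuple[int, int], ...] = field(default=())
    strand_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        parts = self.symbols.split("&")
        if any(len(p) == 0 for p in parts):
            raise StructureError("empty strand in dot-bracket string")
        lengths = tuple(len(p) for p in parts)
        object.__setattr__(self, "strand_lengths", lengths)
        strand_of = self._strand_ids(lengths)
        pairs = []
        stack: list[int] = []
        pos = 0
        for ch in self.symbols:
            if ch == "&":
                continue
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise StructureError(
                        f"unbalanced ')' at residue {pos + 1} in {self.symbols!r}"
                    )
                i = stack.pop()
                if strand_of[i] == strand_of[pos] and pos - i <= self.MIN_HAIRPIN_LOOP:
                    raise StructureError(
                        f"hairpin loop shorter than {self.MIN_HAIRPIN_LOOP} for pair "
                        f"({i + 1},{pos + 1})"
                    )
                pairs.append((i, pos))
            elif ch != ".":
                raise StructureError(f"invalid structure symbol {ch!r}")
            pos += 1
        if stack:
            raise StructureError(f"unbalanced '(' in {self.symbols!r}")
        pairs.sort()
        if self.pair_map and tuple(self.pair_map) != tuple(pairs):
            raise StructureError("pair_map inconsistent with symbols")
        object.__setattr__(self, "pair_map", tuple(pairs))

    @staticmethod
    def _strand_ids(lengths: Sequence[int]) -> np.ndarray:
        return np.repeat(np.arange(len(lengths)), lengths)

    @classmethod
    def from_pairs(
        cls, strand_lengths: Sequence[int], pairs: Iterable[tuple[int, int]]
    ) -> "DotBracketStructure":
        """Build the dot-bracket string for a nested pair set."""
        n = sum(strand_lengths)
        chars = ["."] * n
        for i, j in pairs:
            if not (0 <= i < j < n):
                raise StructureError(f"pair ({i}, {j}) out of range")
            if chars[i] != "." or chars[j] != ".":
                raise StructureError("position paired twice")
            chars[i] = "("
            chars[j] = ")"
        out = []
        pos = 0
        for ln in strand_lengths:
            out.append("".join(chars[pos : pos + ln]))
            pos += ln
        return cls("&".join(out))

    @property
    def residue_length(self) -> int:
        return sum(self.strand_lengths)

    @property
    def n_strands(self) -> int:
        return len(self.strand_lengths)

    @property
    def residue_symbols(self) -> str:
        """Dot-bracket string with strand separators stripped."""
        return self.symbols.replace("&", "")

    def partner_array(self) -> np.ndarray:
        partner = np.full(self.residue_length, -1, dtype=np.int64)
        for i, j in self.pair_map:
            partner[i] = j
            partner[j] = i
        return partner

    def strand_of(self, pos: int) -> int:
        acc = 0
        for s, ln in enumerate(self.strand_lengths):
            acc += ln
            if pos < acc:
                return s
        raise StructureError(f"position {pos} out of range")

    def is_unpaired(self, pos: int) -> bool:
        return self.residue_symbols[pos] == "."


@dataclass(frozen=True)
class ReferenceEnergyModel:
    """Additive pair-energy model: the contract every folding engine follows.

    All pair energies are in kcal/mol and must be non-positive.  GU wobble
    pairs are allowed within a strand by default and disallowed between
    strands (intermolecular contacts are treated as Watson-Crick only).
    """

    gc_energy: float = -3.0
    au_energy: float = -2.0
    gu_energy: float = -1.0
    min_hairpin_loop: int = 3
    allow_gu: bool = True
    allow_gu_intermolecular: bool = False
    enumeration_limit: int = 30
    model_id: str = "reference-additive"

    def __post_init__(self) -> None:
        for e in (self.gc_energy, self.au_energy, self.gu_energy):
            if e > 0:
                raise ParameterError("pair energies must be <= 0 kcal/mol")
        if self.min_hairpin_loop < 0:
            raise ParameterError("min_hairpin_loop must be >= 0")

    def _matrix(self, with_gu: bool) -> np.ndarray:
        # Non-pairable combinations carry +1 so the DP can skip them.
        m = np.full((4, 4), 1.0)
        a, c, g, u = (_BASE_INDEX[b] for b in "ACGU")
        m[g, c] = m[c, g] = self.gc_energy
        m[a, u] = m[u, a] = self.au_energy
        if with_gu:
            m[g, u] = m[u, g] = self.gu_energy
        return m

    def intra_matrix(self) -> np.ndarray:
        return self._matrix(self.allow_gu)

    def inter_matrix(self) -> np.ndarray:
        return self._matrix(self.allow_gu_intermolecular)

    def pair_energy(self, a: str, b: str, same_strand: bool) -> float | None:
        """Energy of pairing bases a-b, or None if not pairable."""
        m = self.intra_matrix() if same_strand else self.inter_matrix()
        e = m[_BASE_INDEX[a], _BASE_INDEX[b]]
        return float(e) if e < 0 else None


@dataclass(frozen=True)
class FoldResult:
    """MFE structure plus its free energy under a declared model."""

    structure: DotBracketStructure
    free_energy: float
    model_id: str
    sequences: tuple[NucleotideSequence, ...] = ()

    @property
    def residues(self) -> str:
        return "".join(s.residues for s in self.sequences)


def _encode(seqs: Sequence[NucleotideSequence]) -> tuple[np.ndarray, np.ndarray]:
    enc = np.array(
        [_BASE_INDEX[b] for s in seqs for b in s.residues], dtype=np.int64
    )
    strand = np.repeat(np.arange(len(seqs)), [len(s) for s in seqs]).astype(np.int64)
    return enc, strand


def _fold_concat(
    seqs: Sequence[NucleotideSequence], model: ReferenceEnergyModel
) -> FoldResult:
    enc, strand = _encode(seqs)
    E = _dp.mfe_matrix(
        enc, strand, model.intra_matrix(), model.inter_matrix(), model.min_hairpin_loop
    )
    partner = _dp.traceback(
        E, enc, strand, model.intra_matrix(), model.inter_matrix(),
        model.min_hairpin_loop,
    )
    pairs = [(int(i), int(partner[i])) for i in range(len(partner)) if partner[i] > i]
    structure = DotBracketStructure.from_pairs([len(s) for s in seqs], pairs)
    energy = float(E[0, len(enc) - 1]) if len(enc) > 1 else 0.0
    return FoldResult(structure, energy, model.model_id, tuple(seqs))


def fold(seq: NucleotideSequence, model: ReferenceEnergyModel) -> FoldResult:
    """Minimum-free-energy pseudoknot-free structure of a single strand.

    Deterministic: ties in the dynamic program are broken by preferring to
    leave the leftmost branching position unpaired.
    """
    return _fold_concat([seq], model)


def cofold(
    seqs: Sequence[NucleotideSequence], model: ReferenceEnergyModel
) -> FoldResult:
    """MFE structure of a 2- or 3-strand complex.

    Strands are concatenated with ``&`` separators; pairing across the
    concatenation is nested-only, and intermolecular pairs are exempt from
    the hairpin-loop minimum.
    """
    if not 2 <= len(seqs) <= 3:
        raise CapabilityError(
            f"cofold supports 2 or 3 strands, got {len(seqs)}"
        )
    return _fold_concat(list(seqs), model)


def evaluate_structure(
    seqs: NucleotideSequence | Sequence[NucleotideSequence],
    structure: DotBracketStructure,
    model: ReferenceEnergyModel,
) -> float:
    """Additive free energy of a given structure: sum of its pair energies."""
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    lengths = tuple(len(s) for s in seqs)
    if lengths != structure.strand_lengths:
        raise StructureError(
            f"sequence strand lengths {lengths} != structure strand lengths "
            f"{structure.strand_lengths}"
        )
    residues = "".join(s.residues for s in seqs)
    strand = DotBracketStructure._strand_ids(lengths)
    total = 0.0
    for i, j in structure.pair_map:
        same = strand[i] == strand[j]
        if same and j - i <= model.min_hairpin_loop:
            raise StructureError(
                f"pair ({i + 1},{j + 1}) violates the hairpin-loop minimum"
            )
        e = model.pair_energy(residues[i], residues[j], bool(same))
        if e is None:
            raise StructureError(
                f"bases {residues[i]}-{residues[j]} at ({i + 1},{j + 1}) cannot pair "
                "under this model"
            )
        total += e
    return total


def enumerate_structures(
    seqs: NucleotideSequence | Sequence[NucleotideSequence],
    model: ReferenceEnergyModel,
) -> Iterator[tuple[tuple[tuple[int, int], ...], float]]:
    """Yield every pseudoknot-free structure with its energy (brute force).

    This is the exhaustive ground-truth oracle behind the MFE tests, the
    reaction-coordinate cross-checks, and the Boltzmann pair-probability
    matrix; it is intentionally independent of the dynamic program.
    """
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    residues = "".join(s.residues for s in seqs)
    n = len(residues)
    if n > model.enumeration_limit:
        raise CapabilityError(
            f"{n} nt exceeds the exhaustive enumeration limit "
            f"({model.enumeration_limit} nt)"
        )
    strand = DotBracketStructure._strand_ids([len(s) for s in seqs])

    def pairable(i: int, k: int) -> float | None:
        same = bool(strand[i] == strand[k])
        if same and k - i <= model.min_hairpin_loop:
            return None
        return model.pair_energy(residues[i], residues[k], same)

    def gen(i: int, j: int) -> Iterator[tuple[tuple[tuple[int, int], ...], float]]:
        if i > j:
            yield (), 0.0
            return
        yield from gen(i + 1, j)
        for k in range(i + 1, j + 1):
            e = pairable(i, k)
            if e is None:
                continue
            for left, el in gen(i + 1, k - 1):
                for right, er in gen(k + 1, j):
                    yield ((i, k),) + left + right, e + el + er

    yield from gen(0, n - 1)


def pair_probabilities(
    seqs: NucleotideSequence | Sequence[NucleotideSequence],
    model: ReferenceEnergyModel,
    rt: float,
) -> np.ndarray:
    """Boltzmann base-pairing probability matrix by exhaustive enumeration.

    Entry (i, j) is the equilibrium probability that residues i and j are
    paired; the matrix is symmetric and each row sums (with the unpaired
    probability) to one.  Restricted to toy sizes by the model's enumeration
    limit.
    """
    if rt <= 0:
        raise ParameterError("RT must be > 0")
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    n = sum(len(s) for s in seqs)
    states = list(enumerate_structures(seqs, model))
    # shift by the minimum energy so low-RT weights cannot overflow
    e_min = min(e for _, e in states)
    P = np.zeros((n, n))
    Z = 0.0
    for pairs, energy in states:
        w = float(np.exp(-(energy - e_min) / rt))
        Z += w
        for i, j in pairs:
            P[i, j] += w
            P[j, i] += w
    P /= Z
    return P
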