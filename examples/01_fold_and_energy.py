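"""Fold single strands and complexes under the reference energy model.

The reference model assigns a fixed energy to each base pair (GC -3, AU -2,
GU -1 kcal/mol) and finds the pseudoknot-free minimum-free-energy (MFE)
structure by dynamic programming — small enough to verify exhaustively,
which is what the package's test oracles do.
"""

from ribodesign import NucleotideSequence, ReferenceEnergyModel, cofold, fold

model = ReferenceEnergyModel()

hairpin = NucleotideSequence("hairpin", "GGGAAAACCC")
result = fold(hairpin, model)
print(f"{hairpin.residues}")
print(f"{result.structure.symbols}  ({result.free_energy:.2f} kcal/mol)")
# three GC pairs close a 4-nt loop: 3 x -3 = -9 kcal/mol

a = NucleotideSequence("a", "GGGG")
b = NucleotideSequence("b", "CCCC")
duplex = cofold([a, b], model)
print(f"\n{a.residues}&{b.residues}")
print(f"{duplex.structure.symbols}  ({duplex.free_energy:.2f} kcal/mol)")
# four intermolecular GC pairs: -12 kcal/mol; pairs between strands are
# exempt from the 3-nt hairpin-loop minimum
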