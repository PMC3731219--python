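"""Trace the association landscape G(r) of two complementary strands.

The reaction coordinate r counts intermolecular Watson-Crick pairs; r = 0
is the state where each strand folds alone.  The profile yields the free
energy of formation (dG, at the complex minimum), the activation energy
(dG_act, at the barrier), and the partition function Z.
"""

from ribodesign import (
    NucleotideSequence,
    ReferenceEnergyModel,
    energies_from_profile,
    enumerate_profile,
)
from ribodesign.landscape import profile_table

model = ReferenceEnergyModel()
a = NucleotideSequence("a", "GGCGAAAACGCC")  # folds into a hairpin alone
b = NucleotideSequence("b", "GGCGUUUU")

profile = enumerate_profile(a, b, model)
print(profile_table(profile))
summary = energies_from_profile(profile, rt=0.61)
print(f"dG (formation)  = {summary.delta_g:.2f} kcal/mol at r = {profile.r_hyb}")
print(f"dG (activation) = {summary.delta_g_activation:.2f} kcal/mol "
      f"at r = {profile.r_trans}")
print(f"Z = {summary.z:.3g}")
# a negative dG means the complex beats the two separate folds; the
# barrier (max of G on the path to r_hyb) is what the seed must cross
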