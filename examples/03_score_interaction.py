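"""Score an sRNA/mRNA pair with the kinetic objective dG_kin.

dG_kin = max(dG, dG_sat) + min(alpha, alpha_sat) * G_p combines how stable
the complex is (dG) with how fast it nucleates (seed length alpha).  With
the printed constants (dG_sat = -15, alpha_sat = 6, G_p = -1.28 kcal/mol)
its best attainable value is -22.68 kcal/mol.
"""

from ribodesign import ObjectiveConfig, ReferenceEnergyModel, default_base_pair
from ribodesign.validation import score_pair

model = ReferenceEnergyModel()
cfg = ObjectiveConfig()
pair = default_base_pair()

dg, alpha, kin = score_pair(pair["sRNA"], pair["mRNA"], model, cfg)
print(f"sRNA : {pair['sRNA'].residues}")
print(f"mRNA : {pair['mRNA'].residues}")
print(f"dG = {dg:.2f} kcal/mol   alpha = {alpha} nt   dG_kin = {kin:.2f}")
print(f"saturated floor = {cfg.dg_sat + cfg.alpha_sat * cfg.g_p:.2f}")
# the more negative dG_kin, the stronger and faster the intended reaction;
# predicted expression fold change scales as exp(-dG_kin / RT)
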