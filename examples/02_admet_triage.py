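"""Rule-based ADMET flags and the lead ranking for the reference panel.

Permeability classes use the 20e-6 cm/s high-permeability cut (a high
class implies ~96% intestinal absorption); stability uses the
hepatocyte (<100, enhanced <20 uL/min/1e6 cells) and microsomal
(<8 uL/min/mg) clearance cuts. The final ranking is lexicographic:
higher desirability score first, then lower mean docking affinity.
"""

from glucotriage.datasets import (affinity_energies, reference_descriptors)
from glucotriage.mpo import CALIBRATED_CONFIG, mpo_score
from glucotriage.pk_triage import PkProfile, classify_permeability, rank_leads

# the lead's predicted MDCK permeability, order 1e-5 cm/s
perm = classify_permeability(1.77e-5, "MDCK")
print(f"MDCK Papp 1.77e-5 cm/s -> class {perm['class']}, "
      f"band {perm['band']}, logPapp {perm['log_papp']:.2f}")

descriptors = reference_descriptors()
scores = {cid: mpo_score(d, CALIBRATED_CONFIG) for cid, d in descriptors.items()}
ea = affinity_energies()
ea_map = {cid: grp["ea_kcal_mol"].tolist()
          for cid, grp in ea.groupby("compound_id") if cid in scores}
ranking = rank_leads({c: scores[c] for c in ea_map}, ea_map)
print("\nranking (desirability, then mean affinity):")
for cid in ranking:
    mean_ea = sum(ea_map[cid]) / len(ea_map[cid])
    print(f"  {cid:<14s} D = {scores[cid].rounded_score:.1f}   "
          f"mean E_A = {mean_ea:7.3f} kcal/mol")
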