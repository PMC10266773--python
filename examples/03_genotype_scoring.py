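"""Score an iKIR/HLA genotype and classify cells by expressed iKIRs.

Each inhibitory KIR gene counts as a functional pair only when the
genome also encodes its HLA ligand: KIR2DL1-C2, KIR2DL2-C1/C2,
KIR2DL3-C1, KIR3DL1-Bw4 (including HLA-A*23/24/32).
"""

from ikirspan import (Genotype, classify_cell, count_functional_ikir,
                      hla_motifs, kir3dl2_filter)

genotype = Genotype.make(
    "donor-01",
    kir={"KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2"},
    hla=("A*24:02", "A*03:01", "B*07:02", "B*57:01", "C*04:01", "C*07:01"),
)

motifs = hla_motifs(genotype.hla_alleles)
print("ligand motifs :", motifs)
score = count_functional_ikir(genotype)
print("functional iKIR-ligand gene pairs :", score.functional_count)
print("inhibitory score (unit weights)   :", score.inhibitory_score)
print("raw iKIR count (ligand-blind)     :", score.raw_ikir_count)
print()

for expressed in ({"KIR2DL1"}, {"KIR2DL2/L3"}, {"KIR3DL1"}, set()):
    label = classify_cell(expressed, genotype)
    name = ", ".join(sorted(expressed)) or "nothing"
    print(f"cell expressing {name:<12} -> {label}")
print()
print("primary-analysis inclusion (excludes KIR3DL2-ligand carriers):",
      kir3dl2_filter(genotype, mode="primary"))
print("sensitivity-analysis inclusion (re-admits A*03/A*11 carriers):",
      kir3dl2_filter(genotype, mode="sensitivity"))
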