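"""Forward models of deuterium enrichment over the three-phase protocol.

A volunteer drinks heavy water: a full dose for 7 days, 2/3 dose until
day 49, then stops.  Body water labels quickly, monocyte DNA follows
with amplification b_w, and a T cell population labels slowly in
proportion to its proliferation rate p.
"""

import numpy as np

from ikirspan import (BodyWaterModel, LabelingProtocol, MonocyteModel,
                      TcellKinetics, monocyte_enrichment, saliva_enrichment,
                      tcell_enrichment)

protocol = LabelingProtocol()                       # 7 / 49 / 112 days
water = BodyWaterModel(f=0.02, delta=0.06, protocol=protocol)
monocytes = MonocyteModel(b_w=4.0, r_2=1.5)
tcells = TcellKinetics(p=1.0 / 125.0, d_star=0.03, delay=3.5)

print(f"T cell lifespan 1/p  : {tcells.lifespan:8.1f} days")
print(f"T cell half-life     : {tcells.half_life:8.1f} days")
print()
print(f"{'day':>4} {'saliva':>9} {'monocyte':>9} {'tcell':>9}")
for t in np.array([0, 7, 14, 21, 35, 49, 63, 84, 112], dtype=float):
    s = saliva_enrichment(t, water)
    m = monocyte_enrichment(t, monocytes, water)
    o = tcell_enrichment(t, tcells, monocytes.b_w, water)
    print(f"{t:4.0f} {s:9.5f} {m:9.5f} {o:9.5f}")

print()
print("The monocyte curve plateaus near b_w * S-plateau ="
      f" {monocytes.b_w * water.plateau():.5f}, which is what makes the"
      " amplification factor identifiable.")
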