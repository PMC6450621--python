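"""Dose-dependent renal handling of a secreted + reabsorbed drug.

A cephalexin-like drug is filtered, secreted (Oat1/Mate1-like) and
reabsorbed by a saturable Pept-like luminal carrier with a small Km. At a
low dose the carrier reclaims most of the luminal drug (clearance ratio
< 1, net reabsorption); at a high dose the carrier saturates and secretion
dominates (ratio > 1).
"""

import renalpk as rp
from renalpk.params import CONTROL_PROFILE
from renalpk.simulator import true_clearances

phys, drug = rp.cephalexin_like()
print(f"GFR {phys.gfr} mL/min/kg, fu {drug.fu}, "
      f"reabsorption Vmax {drug.vmax_reab} nmol/min/kg, Km {drug.km_reab} uM")
print()
for dose in (0.3, 1.0, 3.0, 10.0, 30.0):
    cl_r, cl_tot = true_clearances(phys, drug, CONTROL_PROFILE,
                                   rp.StudyDesign(dose_mg_per_kg=dose))
    res = rp.clearance_ratio(cl_r, drug.fu, phys.gfr)
    print(f"dose {dose:5.1f} mg/kg: CL_R {cl_r:5.2f} mL/min/kg, "
          f"ratio {res.value:4.2f} -> {res.classification}")

print()
print("The clearance ratio rises monotonically with dose and crosses 1")
print("between 1 and 10 mg/kg: saturable reabsorption explains why the")
print("same drug looks net-reabsorbed at a low dose and net-secreted at a")
print("high dose, without any change in transporter expression.")
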