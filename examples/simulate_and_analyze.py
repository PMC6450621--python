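"""Simulate a two-arm disposition study and run it through the NCA pipeline.

A metformin-like flow-limited cation is dosed IV in a control arm and a
'hyperuricemic' arm whose Mate1-like efflux is scaled to 60% expression.
The NCA stage recovers AUC, clearances, kidney partitioning and the
clearance-ratio classification per animal, then summarises by group.
"""

import renalpk as rp
from renalpk.params import CONTROL_PROFILE, TransporterProfile

phys, drug = rp.metformin_like()
design = rp.StudyDesign(dose_mg_per_kg=30.0, n_per_group=5, seed=20)
study = rp.simulate_study(phys, drug, CONTROL_PROFILE,
                          TransporterProfile(theta_efflux=0.6), design,
                          analyte="metformin", compute_truth=False)

per_animal, summary = rp.run_nca_study(
    study.plasma, study.urine, study.tissue, study.doses,
    fu={"metformin": drug.fu},
    gfr={"control": phys.gfr, "hyperuricemic": phys.gfr})

cols = ["analyte", "group", "statistic", "cl_tot", "cl_r",
        "clearance_ratio", "kp_kidney", "urinary_recovery"]
print(summary[cols].round(2).to_string(index=False))
print()
print("Renal clearance is pinned near the fu*Q perfusion cap in both arms")
print("(flow-limited drug), so downregulating the efflux carrier leaves")
print("CL_R and the clearance ratio almost unchanged while the kidney")
print("tissue-to-plasma ratio (K_p) rises — the fold-change row makes the")
print("dissociation explicit.")
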