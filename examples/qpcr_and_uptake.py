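"""Transporter expression (delta-delta-Ct) and MATE1 inhibition assays.

Generates a synthetic 14-gene kidney qPCR panel with several transporters
downregulated, quantifies it with the comparative Ct method, then runs a
MATE1-expressing vs mock cell uptake assay with a cimetidine positive
control through the percent-of-control reduction with Dunnett's test.
"""

import renalpk as rp

TRUE_RATIOS = {  # case/control expression; < 1 = downregulated
    "Mate1": 0.6, "Oct2": 0.55, "Oat1": 0.5, "Urat1": 0.45, "Pept1": 0.6,
    "Oat3": 0.9, "Oct1": 0.95, "Mate2k": 1.0, "Pept2": 0.85, "Mdr1a": 1.0,
    "Mrp2": 1.05, "Mrp4": 0.9, "Bcrp": 0.9, "Glut9": 1.0,
}

ct = rp.generate_qpcr(TRUE_RATIOS, n_per_group=6, noise_sd_ct=0.25, seed=42)
_, summary = rp.delta_delta_ct(ct, reference_gene="Gapdh",
                               control_group="control")
case = summary[summary.group == "hyperuricemic"].set_index("gene")
print("gene     true   estimated ratio-to-control")
for gene, true in sorted(TRUE_RATIOS.items()):
    est = float(case.loc[gene, "ratio_to_control"])
    print(f"{gene:8s} {true:4.2f}   {est:4.2f}")
print()

records = rp.generate_uptake(
    mate1_component=100.0, background=20.0,
    inhibition_fraction={"oxonic acid 500uM": 0.02, "adenine 500uM": 0.13,
                         "uric acid 500uM": 0.0, "cimetidine": 0.918},
    n=3, noise_cv=0.05, seed=42)
table = rp.reduce_uptake_study(records, n_draws=50_000)
print(table.round({"percent_of_control": 1, "p_adj": 4}).to_string(index=False))
print()
print("Only the cimetidine positive control abolishes MATE1-mediated MPP+")
print("uptake (under 10% of control, Dunnett p << 0.05); the hyperuricemia-")
print("inducing agents themselves do not inhibit the transporter, so the")
print("in-vivo changes must come from expression, not direct inhibition.")
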