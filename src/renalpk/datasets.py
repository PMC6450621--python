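"""Published group-level summary statistics of the hyperuricemic-rat study.

These are the reported group means (± SEM, n = 3 unless noted) for the
control vs hyperuricemic rat disposition study of metformin (30 mg/kg IV),
cephalexin (1 or 10 mg/kg IV) and endogenous creatinine, together with the
kidney-function panel, the MATE1-expressing-cell inhibition percentages and
the Mate1 protein ratio. They serve as desk-scale inputs for the
clearance-ratio and fold-change arithmetic and as reference points for the
simulator's qualitative behaviour. NaN marks entries reported as not
calculated (NC) or not applicable (NA).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "kidney_function_panel",
    "pk_parameters_by_group",
    "cephalexin_dose_comparison",
    "uptake_percent_of_control",
    "FU",
    "MATE1_PROTEIN_RATIO",
]

NA = float("nan")

#: Plasma unbound fractions used throughout the study (creatinine set to 1).
FU = {"metformin": 0.85, "cephalexin": 0.82, "creatinine": 1.0, "inulin": 1.0}

#: Reported Mate1 protein level in hyperuricemic kidney relative to control.
MATE1_PROTEIN_RATIO = 0.607


def kidney_function_panel() -> pd.DataFrame:
    """BUN, plasma creatinine and inulin clearance (GFR) per group."""
    return pd.DataFrame(
        [
            ("control", 15.4, 1.2, 12.8, 0.1, 6.72, 0.46),
            ("hyperuricemic", 34.2, 1.5, 33.6, 3.9, 5.36, 0.77),
        ],
        columns=["group", "bun_mg_dL", "bun_sem", "plasma_creatinine_uM",
                 "plasma_creatinine_sem", "cl_inulin_mL_min_kg", "cl_inulin_sem"],
    )


def pk_parameters_by_group() -> pd.DataFrame:
    """Group-mean PK parameters: metformin, cephalexin 10 mg/kg, creatinine.

    Columns: AUC_0-4 and AUC_inf in µM·min, CL_R in mL/min/kg, fu,
    printed (CL_R/fu)/CL_inulin ratio, urinary recovery in % of dose/4 h,
    and K_p,kidney.
    """
    cols = ["analyte", "group", "dose_mg_per_kg", "auc_0_4", "auc_inf",
            "cl_r", "fu", "clearance_ratio_printed", "urinary_recovery",
            "kp_kidney"]
    return pd.DataFrame(
        [
            ("metformin", "control", 30.0, 5530.0, 5638.0, 23.0, 0.85, 4.03, 74.5, 16.6),
            ("metformin", "hyperuricemic", 30.0, 6100.0, 6223.0, 18.3, 0.85, 4.01, 63.3, 90.3),
            ("cephalexin", "control", 10.0, 2629.0, 2770.0, 7.96, 0.82, 1.44, 71.0, 9.76),
            ("cephalexin", "hyperuricemic", 10.0, 4625.0, 7381.0, 2.87, 0.82, 0.65, 46.1, 15.1),
            ("creatinine", "control", 0.0, 5373.0, NA, 10.9, 1.0, 1.62, NA, 10.2),
            ("creatinine", "hyperuricemic", 0.0, 9807.0, NA, 5.84, 1.0, 1.09, NA, 13.7),
        ],
        columns=cols,
    )


def cephalexin_dose_comparison() -> pd.DataFrame:
    """Cephalexin in control rats at 1 vs 10 mg/kg IV (dose-dependence)."""
    cols = ["dose_mg_per_kg", "auc_0_4", "auc_inf", "cl_tot", "cl_r",
            "cl_creatinine", "fu", "clearance_ratio_printed",
            "urinary_recovery"]
    return pd.DataFrame(
        [
            (1.0, 656.0, 901.0, 3.57, 1.88, 7.66, 0.82, 0.34, 41.1),
            (10.0, 2629.0, 2770.0, 10.6, 7.96, 10.9, 0.82, 1.44, 71.0),
        ],
        columns=cols,
    )


def uptake_percent_of_control() -> pd.DataFrame:
    """Reported percent-of-control MATE1-mediated MPP+ uptake."""
    return pd.DataFrame(
        [
            ("oxonic acid", 50.0, 101.5),
            ("oxonic acid", 500.0, 98.2),
            ("adenine", 50.0, 87.7),
            ("adenine", 500.0, 87.0),
            ("uric acid", 50.0, 102.0),
            ("uric acid", 500.0, 100.7),
            ("cimetidine", 500.0, 8.2),
        ],
        columns=["treatment", "conc_uM", "percent_of_control"],
    )
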