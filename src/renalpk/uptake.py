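"""Cell uptake assay reduction for transporter-expressing vs mock cells.

Uptake is expressed as a cell-to-medium ratio (µL/mg protein); the
transporter-mediated component is the expressing-cell mean minus the
treatment-matched mock-cell mean, and inhibition is reported as percent of
the untreated control's transporter-mediated component.
"""

from __future__ import annotations

import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .stats import dunnett_many_to_one

__all__ = ["cell_to_medium", "percent_of_control", "reduce_uptake_study"]


def cell_to_medium(amount_pmol_per_mg: float, medium_conc_pmol_per_uL: float) -> float:
    """Cell-to-medium ratio in µL/mg protein."""
    if medium_conc_pmol_per_uL <= 0:
        raise ValidationError("medium concentration must be positive")
    if amount_pmol_per_mg < 0:
        raise ValidationError("uptake amount must be non-negative")
    return amount_pmol_per_mg / medium_conc_pmol_per_uL


def percent_of_control(expressing_treated: float, mock_treated: float,
                       expressing_control: float, mock_control: float) -> float:
    """Percent of control of the transporter-mediated uptake component.

    100 * (expressing_treated - mock_treated) /
          (expressing_control - mock_control),
    all four arguments being group means of cell-to-medium ratios. Mock
    subtraction is treatment-matched.
    """
    denom = expressing_control - mock_control
    if denom <= 0:
        raise UndefinedRatioError(
            "control transporter-mediated component must be positive")
    return 100.0 * (expressing_treated - mock_treated) / denom


def reduce_uptake_study(records: pd.DataFrame, control_treatment: str = "control",
                        dunnett_seed: int = 0, n_draws: int = 100_000,
                        ) -> pd.DataFrame:
    """Percent-of-control table (with Dunnett p values) from tidy records.

    ``records`` columns: ``cell_line`` (expressing/mock), ``treatment``,
    ``replicate``, ``amount_pmol_per_mg``, ``medium_conc_pmol_per_uL``.
    Dunnett's many-to-one test compares expressing-cell cell-to-medium
    ratios of every treatment against the control treatment.
    """
    required = {"cell_line", "treatment", "replicate",
                "amount_pmol_per_mg", "medium_conc_pmol_per_uL"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"uptake table missing columns: {sorted(missing)}")
    df = records.copy()
    df["c2m"] = df["amount_pmol_per_mg"] / df["medium_conc_pmol_per_uL"]
    means = df.groupby(["treatment", "cell_line"])["c2m"].mean().unstack()
    if control_treatment not in means.index:
        raise ValidationError(f"no treatment labelled {control_treatment!r}")
    for cl in ("expressing", "mock"):
        if cl not in means.columns:
            raise ValidationError(f"no {cl!r} cell-line records")
    exp_c = float(means.loc[control_treatment, "expressing"])
    mock_c = float(means.loc[control_treatment, "mock"])

    ctrl_vals = df[(df["treatment"] == control_treatment)
                   & (df["cell_line"] == "expressing")]["c2m"].to_numpy()
    treatments = [t for t in means.index if t != control_treatment]
    rows = [{"treatment": control_treatment, "percent_of_control": 100.0,
             "p_adj": float("nan")}]
    if treatments:
        groups = [df[(df["treatment"] == t) & (df["cell_line"] == "expressing")]
                  ["c2m"].to_numpy() for t in treatments]
        try:
            p_adj = dunnett_many_to_one(ctrl_vals, groups, seed=dunnett_seed,
                                        n_draws=n_draws)
        except ValidationError:
            # degenerate (noise-free or single-replicate) data: no inference
            p_adj = [float("nan")] * len(groups)
        for t, p in zip(treatments, p_adj):
            rows.append({
                "treatment": t,
                "percent_of_control": percent_of_control(
                    float(means.loc[t, "expressing"]), float(means.loc[t, "mock"]),
                    exp_c, mock_c),
                "p_adj": float(p),
            })
    return pd.DataFrame(rows)
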