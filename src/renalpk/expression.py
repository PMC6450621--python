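"""Relative mRNA quantification by the comparative Ct (delta-delta-Ct) method.

Per sample, the target gene's Ct is normalised to the reference gene
(delta Ct = Ct_gene - Ct_ref), then referenced to the mean delta Ct of the
control group; relative expression is 2^(-ddCt) assuming amplification
efficiency 2. Group means are renormalised so the control group displays
exactly 1, and case groups as the ratio to control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import mean_sem

__all__ = ["delta_delta_ct"]


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str = "Gapdh",
                   control_group: str = "control",
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression from a tidy Ct table.

    Parameters
    ----------
    ct
        Columns ``sample_id, group, gene, ct``. Technical replicates
        (duplicate sample × gene rows) are averaged on the Ct scale first.
    reference_gene, control_group
        Normalisation gene (must be present for every sample) and the
        group whose mean expression defines the baseline.

    Returns
    -------
    per_sample
        One row per sample × gene (reference gene included, with relative
        expression identically 1) carrying ``delta_ct``, ``ddct`` and
        ``rel_expr`` = 2^(-ddCt).
    summary
        Per gene × group mean ± SEM of relative expression, with
        ``ratio_to_control`` scaled so the control-group mean is exactly 1.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(ct["ct"].to_numpy(dtype=float))):
        raise ValidationError("all Ct values must be finite")
    if control_group not in set(ct["group"]):
        raise ValidationError(f"unknown control group label {control_group!r}")

    # average technical replicates on the Ct scale
    tidy = (ct.groupby(["sample_id", "group", "gene"], as_index=False)["ct"]
              .mean())
    ref = tidy[tidy["gene"] == reference_gene].set_index("sample_id")["ct"]
    samples = tidy["sample_id"].unique()
    lacking = sorted(set(samples) - set(ref.index))
    if lacking:
        raise ValidationError(
            f"samples missing reference gene {reference_gene!r}: {lacking}")

    targets = tidy.copy()  # reference gene kept: its ddCt is 0 by construction
    targets["delta_ct"] = (targets["ct"].to_numpy()
                           - ref.loc[targets["sample_id"]].to_numpy())
    rows = []
    for gene, g in targets.groupby("gene", sort=True):
        ctrl = g.loc[g["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            raise ValidationError(f"gene {gene!r} has no control-group samples")
        baseline = float(ctrl.mean())
        g = g.assign(ddct=g["delta_ct"] - baseline)
        g = g.assign(rel_expr=np.exp2(-g["ddct"]))
        rows.append(g)
    per_sample = pd.concat(rows, ignore_index=True)

    summary_rows = []
    for gene, g in per_sample.groupby("gene", sort=True):
        ctrl_mean = float(g.loc[g["group"] == control_group, "rel_expr"].mean())
        for group, gg in g.groupby("group", sort=True):
            s = mean_sem(gg["rel_expr"].to_numpy())
            summary_rows.append({
                "gene": gene, "group": group, "n": s.n,
                "rel_expr_mean": s.mean, "rel_expr_sem": s.sem,
                "ratio_to_control": s.mean / ctrl_mean,
            })
    summary = pd.DataFrame(summary_rows)
    return per_sample, summary
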