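"""Tidy CSV schemas, validated readers and deterministic report writers.

One row per observation; units are baked into column names so unit drift
is caught at the file boundary. Unknown extra columns are accepted with a
warning for forward compatibility; missing columns, non-numeric cells and
negative concentrations/amounts are rejected with file/row/column context.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import LayoutError, SchemaError

__all__ = ["SCHEMAS", "read_validate", "write_table", "write_report",
           "write_sidecar", "read_sidecar"]

#: schema name -> {column: (dtype kind, non_negative)}
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "plasma": {
        "subject_id": ("str", False), "group": ("str", False),
        "analyte": ("str", False), "time_min": ("num", True),
        "conc_uM": ("num", True),
    },
    "urine": {
        "subject_id": ("str", False), "group": ("str", False),
        "analyte": ("str", False), "t_start_min": ("num", True),
        "t_end_min": ("num", True), "amount_nmol_per_kg": ("num", True),
    },
    "tissue": {
        "subject_id": ("str", False), "group": ("str", False),
        "analyte": ("str", False), "time_min": ("num", True),
        "conc_uM": ("num", True),
    },
    "doses": {
        "subject_id": ("str", False), "analyte": ("str", False),
        "dose_mg_per_kg": ("num", True), "mw_g_per_mol": ("num", True),
    },
    "fu": {
        "analyte": ("str", False), "fu": ("num", True), "source": ("str", False),
    },
    "gfr": {
        "group": ("str", False), "cl_inulin_mL_min_kg": ("num", True),
    },
    "ct": {
        "sample_id": ("str", False), "group": ("str", False),
        "gene": ("str", False), "ct": ("num", False),
    },
    "uptake": {
        "cell_line": ("str", False), "treatment": ("str", False),
        "replicate": ("str", False), "amount_pmol_per_mg": ("num", True),
        "medium_conc_pmol_per_uL": ("num", True),
    },
}


def read_validate(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Returns a typed DataFrame with the schema columns first, in schema
    order. Raises :class:`SchemaError` naming file, row (1-based data row)
    and column for every violation.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing} "
                          f"for schema {schema_name!r}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)

    out = {}
    for col, (kind, non_negative) in schema.items():
        raw = df[col]
        if kind == "num":
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & raw.notna()
            if raw.isna().any():
                row = int(raw[raw.isna()].index[0]) + 1
                raise SchemaError(f"{path}: row {row}, column {col!r}: empty cell")
            if bad.any():
                row = int(bad[bad].index[0]) + 1
                raise SchemaError(
                    f"{path}: row {row}, column {col!r}: "
                    f"non-numeric value {raw[bad].iloc[0]!r}")
            if non_negative and (vals < 0).any():
                row = int(vals[vals < 0].index[0]) + 1
                raise SchemaError(
                    f"{path}: row {row}, column {col!r}: negative value "
                    f"{vals[vals < 0].iloc[0]}")
            out[col] = vals.astype(float)
        else:
            if raw.isna().any():
                row = int(raw[raw.isna()].index[0]) + 1
                raise SchemaError(f"{path}: row {row}, column {col!r}: empty cell")
            out[col] = raw.astype(str)
    result = pd.DataFrame(out)
    for c in extra:
        result[c] = df[c]
    return result


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV with deterministic column order and formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


# Report layouts: (column, header, decimals); None decimals = raw/string.
_LAYOUTS: dict[str, list[tuple[str, str, int | None]]] = {
    "kidney_function": [
        ("group", "Group", None),
        ("bun_mg_dL", "BUN (mg/dL)", 1),
        ("plasma_creatinine_uM", "Plasma Creatinine (uM)", 1),
        ("cl_inulin_mL_min_kg", "Inulin Clearance (mL/min/kg)", 2),
    ],
    "pk_summary": [
        ("analyte", "Compound", None),
        ("group", "Group", None),
        ("statistic", "Statistic", None),
        ("auc_0_t", "AUC_0-4 (uM*min)", 0),
        ("auc_inf", "AUC_inf (uM*min)", 0),
        ("cl_tot", "CL_tot (mL/min/kg)", 2),
        ("cl_r", "CL_R (mL/min/kg)", 2),
        ("clearance_ratio", "(CL_R/fu)/CL_inulin", 2),
        ("urinary_recovery", "Urinary Recovery (% of Dose/4 h)", 1),
        ("kp_kidney", "K_p,kidney", 2),
    ],
    "expression": [
        ("gene", "Gene", None),
        ("group", "Group", None),
        ("n", "n", None),
        ("ratio_to_control", "Ratio to control", 2),
        ("rel_expr_sem", "SEM", 2),
    ],
    "uptake": [
        ("treatment", "Treatment", None),
        ("percent_of_control", "Percent of control (%)", 1),
        ("p_adj", "Dunnett adjusted p", 4),
    ],
}


def write_report(results: pd.DataFrame, layout: str, path: str | Path) -> Path:
    """Write a rounded, human-readable summary CSV in a named layout.

    Missing layout columns raise :class:`LayoutError`; an empty results
    table produces a header-only file. Output is byte-deterministic for
    identical inputs: fixed column order, fixed rounding (2 decimals for
    ratio-type columns, matching how such tables are printed).
    """
    if layout not in _LAYOUTS:
        raise LayoutError(f"unknown layout {layout!r}; "
                          f"available: {sorted(_LAYOUTS)}")
    spec = _LAYOUTS[layout]
    if len(results):
        missing = [col for col, _, _ in spec if col not in results.columns]
        if missing:
            raise LayoutError(f"layout {layout!r} needs columns {missing}")
    out = pd.DataFrame()
    for col, header, decimals in spec:
        if not len(results):
            out[header] = pd.Series(dtype=object)
            continue
        vals = results[col]
        if decimals is not None:
            vals = pd.to_numeric(vals, errors="coerce").round(decimals)
            if decimals == 0:
                vals = vals.astype("Int64")
        out[header] = vals
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_sidecar(params: dict, path: str | Path, seed: int | None = None) -> Path:
    """Write a YAML provenance sidecar: parameters, seed, config hash, version."""
    from . import __version__
    payload = {"parameters": params, "seed": seed, "tool_version": __version__}
    blob = yaml.safe_dump(params, sort_keys=True).encode()
    payload["config_sha256"] = hashlib.sha256(blob).hexdigest()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
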