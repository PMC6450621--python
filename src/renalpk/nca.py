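"""Non-compartmental pharmacokinetic analysis.

Implements the classic IV-bolus NCA workflow: linear-trapezoid AUC over a
window, terminal log-linear slope (lambda_z) with adjusted-R² window
selection, extrapolated AUC_inf, total and renal clearance, urinary
recovery, the kidney-to-plasma partition coefficient, and the
fu/GFR-normalised renal clearance ratio used to classify net tubular
secretion versus net reabsorption. ``run_nca_study`` assembles per-animal
results and group summaries (mean ± SEM with case/control fold changes)
from tidy tables.

Units: time min, concentration µM (= nmol/mL), amounts nmol/kg, clearances
mL/min/kg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    NoValidFitError,
    UndefinedRatioError,
    ValidationError,
)
from .stats import mean_sem

__all__ = [
    "ConcentrationTimeProfile",
    "UrineCollection",
    "DoseRecord",
    "LambdaZFit",
    "NCAResult",
    "auc_linear_trapezoid",
    "fit_lambda_z",
    "auc_extrapolate_inf",
    "cl_total",
    "cl_renal",
    "urinary_recovery",
    "kp_kidney",
    "clearance_ratio",
    "fold_change",
    "run_nca_study",
]


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One animal × analyte plasma concentration-time series."""

    subject_id: str
    group: str
    analyte: str
    times: np.ndarray   # min, strictly increasing
    conc: np.ndarray    # µM, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.size != c.size:
            raise ValidationError("times and conc must have equal length")
        if t.size < 2:
            raise ValidationError("a profile needs at least 2 points")
        if t[0] < 0:
            raise ValidationError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing (no duplicates)")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValidationError("concentrations must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)


@dataclass(frozen=True)
class UrineCollection:
    """Interval urine amounts for one animal × analyte."""

    subject_id: str
    analyte: str
    intervals: tuple[tuple[float, float], ...]
    amounts: np.ndarray  # nmol/kg per interval

    def __post_init__(self):
        ivs = tuple(tuple(map(float, iv)) for iv in self.intervals)
        x = np.asarray(self.amounts, dtype=float)
        if len(ivs) != x.size:
            raise ValidationError("one amount per interval required")
        ordered = sorted(ivs)
        for (a, b) in ordered:
            if not b > a >= 0:
                raise ValidationError(f"degenerate urine interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ordered, ordered[1:]):
            if a1 < b0:
                raise ValidationError("urine intervals overlap")
        if np.any(x < 0):
            raise ValidationError("urine amounts must be non-negative")
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "amounts", x)


@dataclass(frozen=True)
class DoseRecord:
    """IV bolus dose; mw converts mg/kg to nmol/kg."""

    dose_mg_per_kg: float
    mw: float

    def __post_init__(self):
        if self.dose_mg_per_kg < 0:
            raise ValidationError("dose must be non-negative")
        if self.mw <= 0:
            raise ValidationError("mw must be positive")

    @property
    def dose_umol_per_kg(self) -> float:
        return self.dose_mg_per_kg * 1000.0 / self.mw

    @property
    def dose_nmol_per_kg(self) -> float:
        return self.dose_mg_per_kg * 1e6 / self.mw


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear elimination fit."""

    lambda_z: float      # 1/min
    n_points: int
    adj_r_squared: float
    t_first: float
    t_last: float

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.lambda_z


@dataclass(frozen=True)
class NCAResult:
    """Per-animal derived parameters; NaN marks not-calculable entries."""

    subject_id: str
    group: str
    analyte: str
    auc_0_t: float
    auc_inf: float
    cl_tot: float
    cl_r: float
    urinary_recovery: float
    kp_kidney: float
    clearance_ratio: float
    classification: str


def auc_linear_trapezoid(profile: ConcentrationTimeProfile,
                         t_start: float = 0.0, t_end: float | None = None,
                         anchor_t0: bool = True) -> float:
    """Linear-trapezoid AUC of the profile over [t_start, t_end], µM·min.

    For an IV bolus no concentration is measurable at t = 0; by default the
    first observed concentration is carried back to the window start
    (constant anchoring, no back-extrapolation). Requesting time beyond the
    last sample raises, since extrapolation belongs to ``auc_extrapolate_inf``.
    """
    t, c = profile.times, profile.conc
    if t_end is None:
        t_end = float(t[-1])
    if t_end <= t_start:
        raise ValidationError("t_end must exceed t_start")
    if t_end > t[-1] + 1e-9:
        raise ValidationError(
            f"window end {t_end} min beyond last sample {t[-1]} min")
    if t_start < t[0]:
        if not anchor_t0:
            raise ValidationError(
                f"window start {t_start} min precedes first sample {t[0]} min "
                "and anchoring is disabled")
        t = np.concatenate([[t_start], t])
        c = np.concatenate([[c[0]], c])
    grid = np.unique(np.concatenate([t[(t >= t_start) & (t <= t_end)],
                                     [t_start, t_end]]))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def fit_lambda_z(profile: ConcentrationTimeProfile,
                 min_points: int = 3) -> LambdaZFit:
    """Terminal slope by log-linear OLS with adjusted-R² window selection.

    Candidate windows are the last m post-peak points for m = min_points
    up to all post-peak points; the window with the highest adjusted R²
    wins, ties going to fewer points. Raises :class:`NoValidFitError` when
    no window has all-positive concentrations and a negative slope.
    """
    t, c = profile.times, profile.conc
    peak = int(np.argmax(c))
    t, c = t[peak:], c[peak:]
    n = t.size
    if n < min_points:
        raise NoValidFitError(
            f"only {n} post-peak points; at least {min_points} required")
    best: LambdaZFit | None = None
    for m in range(min_points, n + 1):
        tw, cw = t[-m:], c[-m:]
        if np.any(cw <= 0):
            continue
        y = np.log(cw)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:  # flat in log space: no elimination information
            continue
        slope, intercept = np.polyfit(tw, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * tw + intercept)
        ss_res = float(resid @ resid)
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        # strict > keeps the earlier (fewer-point) window on ties
        if best is None or adj > best.adj_r_squared + 1e-12:
            best = LambdaZFit(lambda_z=-float(slope), n_points=m,
                              adj_r_squared=float(adj),
                              t_first=float(tw[0]), t_last=float(tw[-1]))
    if best is None:
        raise NoValidFitError(
            "no terminal window with positive concentrations and negative slope")
    return best


def auc_extrapolate_inf(auc_0_tlast: float, c_last: float,
                        fit: LambdaZFit) -> float:
    """AUC_inf = AUC_0-tlast + C_last / lambda_z."""
    if c_last < 0:
        raise ValidationError("c_last must be non-negative")
    return auc_0_tlast + c_last / fit.lambda_z


def cl_total(dose: DoseRecord, auc_inf: float) -> float:
    """Total clearance D / AUC_inf in mL/min/kg."""
    if dose.dose_mg_per_kg == 0:
        return 0.0
    if auc_inf <= 0:
        raise UndefinedRatioError(
            f"AUC_inf must be positive to compute CL_tot (got {auc_inf})")
    return dose.dose_nmol_per_kg / auc_inf


def cl_renal(urine: UrineCollection, auc_0_t: float,
             window: tuple[float, float] = (0.0, 240.0)) -> float:
    """Renal clearance X_urine(window) / AUC(window) in mL/min/kg.

    The union of collection intervals must cover the window; gaps raise a
    :class:`CoverageError` listing the missing spans.
    """
    if auc_0_t <= 0:
        raise UndefinedRatioError("AUC over the window must be positive")
    w0, w1 = float(window[0]), float(window[1])
    covered = sorted((max(a, w0), min(b, w1)) for a, b in urine.intervals
                     if b > w0 and a < w1)
    gaps, cursor = [], w0
    for a, b in covered:
        if a > cursor + 1e-9:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < w1 - 1e-9:
        gaps.append((cursor, w1))
    if gaps:
        raise CoverageError(gaps)
    total = sum(x for (a, b), x in zip(urine.intervals, urine.amounts)
                if a >= w0 - 1e-9 and b <= w1 + 1e-9)
    return total / auc_0_t


def urinary_recovery(urine: UrineCollection, dose: DoseRecord,
                     window: tuple[float, float] = (0.0, 240.0)) -> float:
    """Percent of dose recovered in urine over the window."""
    if dose.dose_mg_per_kg <= 0:
        raise UndefinedRatioError(
            "urinary recovery is undefined for zero dose (endogenous analyte)")
    w0, w1 = window
    total = sum(x for (a, b), x in zip(urine.intervals, urine.amounts)
                if a >= w0 - 1e-9 and b <= w1 + 1e-9)
    return 100.0 * total / dose.dose_nmol_per_kg


def kp_kidney(c_kidney: float, c_plasma: float) -> float:
    """Kidney tissue-to-plasma concentration ratio."""
    if c_plasma <= 0:
        raise UndefinedRatioError("plasma concentration must be positive for K_p")
    if c_kidney < 0:
        raise ValidationError("kidney concentration must be non-negative")
    return c_kidney / c_plasma


@dataclass(frozen=True)
class ClearanceRatio:
    value: float
    classification: str  # net-secretion / net-reabsorption / indeterminate


def clearance_ratio(cl_r: float, fu: float, cl_inulin: float,
                    epsilon: float = 0.05) -> ClearanceRatio:
    """(CL_R / fu) / CL_inulin with net-transport classification.

    Ratios above 1 indicate net tubular secretion, below 1 net
    reabsorption; an epsilon band around 1 (default ±0.05) is classified
    indeterminate. Set epsilon = 0 for the strict >1/<1 rule.
    """
    if not 0 < fu <= 1:
        raise ValidationError("fu must lie in (0, 1]")
    if cl_inulin <= 0:
        raise ValidationError("cl_inulin (GFR) must be positive")
    if cl_r < 0:
        raise ValidationError("cl_r must be non-negative")
    if epsilon < 0:
        raise ValidationError("epsilon must be non-negative")
    value = (cl_r / fu) / cl_inulin
    if value > 1.0 + epsilon:
        cls = "net-secretion"
    elif value < 1.0 - epsilon:
        cls = "net-reabsorption"
    else:
        cls = "indeterminate"
    return ClearanceRatio(value=value, classification=cls)


def fold_change(mean_case: float, mean_control: float) -> float:
    """Case/control ratio of group means."""
    if mean_control == 0:
        raise ValidationError("control mean must be non-zero for a fold change")
    return mean_case / mean_control


# ---------------------------------------------------------------------------
# Study-level assembly

_PARAM_COLS = ["auc_0_t", "auc_inf", "cl_tot", "cl_r",
               "clearance_ratio", "urinary_recovery", "kp_kidney"]


def run_nca_study(plasma: pd.DataFrame, urine: pd.DataFrame | None,
                  tissue: pd.DataFrame | None, doses: pd.DataFrame | None,
                  fu: dict[str, float], gfr: dict[str, float],
                  window: tuple[float, float] = (0.0, 240.0),
                  control_group: str = "control",
                  epsilon: float = 0.05,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-animal NCA plus group summary for a tidy study bundle.

    Parameters use the tidy CSV schemas (see :mod:`renalpk.io`). ``fu`` maps
    analyte -> unbound fraction, ``gfr`` maps group -> inulin clearance in
    mL/min/kg. Analytes without a positive dose record are treated as
    endogenous: AUC_inf, CL_tot and recovery are reported NaN (printed
    "NC"/"NA"), as is AUC_inf whenever no terminal slope can be fit.

    Returns (per-animal table, group summary). The summary holds mean and
    SEM per group × analyte × parameter plus a case/control fold-change row
    for every non-control group.
    """
    for analyte in plasma["analyte"].unique():
        if analyte not in fu:
            raise ValidationError(f"no fu configured for analyte {analyte!r}")
    dose_map = {}
    if doses is not None and len(doses):
        for r in doses.itertuples(index=False):
            dose_map[(r.subject_id, r.analyte)] = DoseRecord(
                float(r.dose_mg_per_kg), float(r.mw_g_per_mol))

    results: list[NCAResult] = []
    for (sid, group, analyte), g in plasma.groupby(
            ["subject_id", "group", "analyte"], sort=True):
        g = g.sort_values("time_min")
        profile = ConcentrationTimeProfile(
            sid, group, analyte, g["time_min"].to_numpy(), g["conc_uM"].to_numpy())
        auc_w = auc_linear_trapezoid(profile, window[0], window[1])

        dose = dose_map.get((sid, analyte))
        endogenous = dose is None or dose.dose_mg_per_kg == 0
        auc_inf = cl_t = math.nan
        if not endogenous:
            try:
                fit = fit_lambda_z(profile)
                auc_all = auc_linear_trapezoid(profile, window[0], profile.times[-1])
                auc_inf = auc_extrapolate_inf(auc_all, float(profile.conc[-1]), fit)
                cl_t = cl_total(dose, auc_inf)
            except NoValidFitError as exc:
                warnings.warn(f"{sid}/{analyte}: AUC_inf not calculable ({exc})",
                              stacklevel=2)

        clr = recov = math.nan
        if urine is not None and len(urine):
            u = urine[(urine["subject_id"] == sid) & (urine["analyte"] == analyte)]
            if len(u):
                coll = UrineCollection(
                    sid, analyte,
                    tuple(zip(u["t_start_min"], u["t_end_min"])),
                    u["amount_nmol_per_kg"].to_numpy())
                clr = cl_renal(coll, auc_w, window)
                if not endogenous:
                    recov = urinary_recovery(coll, dose, window)

        kp = math.nan
        if tissue is not None and len(tissue):
            tt = tissue[(tissue["subject_id"] == sid) & (tissue["analyte"] == analyte)]
            if len(tt):
                c_kid = float(tt["conc_uM"].iloc[0])
                t_kid = float(tt["time_min"].iloc[0])
                c_pl = float(np.interp(t_kid, profile.times, profile.conc))
                if c_pl > 0:
                    kp = kp_kidney(c_kid, c_pl)

        ratio_val, cls = math.nan, "indeterminate"
        if not math.isnan(clr) and group in gfr:
            cr = clearance_ratio(clr, fu[analyte], gfr[group], epsilon)
            ratio_val, cls = cr.value, cr.classification

        results.append(NCAResult(sid, group, analyte, auc_w, auc_inf, cl_t,
                                 clr, recov, kp, ratio_val, cls))

    per_animal = pd.DataFrame([r.__dict__ for r in results])
    summary = _summarise(per_animal, control_group)
    return per_animal, summary


def _summarise(per_animal: pd.DataFrame, control_group: str) -> pd.DataFrame:
    rows = []
    for (analyte, group), g in per_animal.groupby(["analyte", "group"], sort=True):
        row = {"analyte": analyte, "group": group, "statistic": "mean±sem",
               "n": len(g)}
        for col in _PARAM_COLS:
            vals = g[col].dropna().to_numpy()
            if vals.size:
                s = mean_sem(vals)
                row[col], row[f"{col}_sem"] = s.mean, s.sem
            else:
                row[col] = row[f"{col}_sem"] = math.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    controls = summary[summary["group"] == control_group].set_index("analyte")
    for (analyte, group), g in summary.groupby(["analyte", "group"], sort=True):
        if group == control_group or analyte not in controls.index:
            continue
        fc = {"analyte": analyte, "group": group, "statistic": "fold-change",
              "n": int(g["n"].iloc[0])}
        for col in _PARAM_COLS:
            case_m = float(g[col].iloc[0])
            ctrl_m = float(controls.loc[analyte, col])
            fc[col] = (fold_change(case_m, ctrl_m)
                       if not (math.isnan(case_m) or math.isnan(ctrl_m)
                               or ctrl_m == 0) else math.nan)
            fc[f"{col}_sem"] = math.nan
        rows.append(fc)
    return pd.DataFrame(rows)
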