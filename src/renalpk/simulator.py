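"""Mechanistic renal tubular transport simulator.

The disposition model has four mass compartments (amounts in nmol/kg):

* central plasma (``A_c``, volume ``v_central``),
* proximal tubular cells (``A_k``, volume ``v_kidney``),
* tubular lumen (``A_l``, volume ``v_lumen``),
* urine (``A_u``, absorbing).

Glomerular filtration removes unbound drug at the systemic concentration
(``fu * GFR * C_p``), so a freely filtered marker's renal clearance equals
GFR by construction, matching how GFR is measured as inulin clearance.
Carrier-mediated secretion is flow-limited: it draws on the postglomerular
peritubular plasma flow ``Q_pt = q_renal - gfr``, and at each instant a
local peritubular concentration ``C_local`` is solved from the flow balance

    Q_pt * fu * (C_p - C_local) =
        J_uptake(fu * C_local) + PS * (fu * C_local - C_cell)

by bracketed scalar root finding. Total renal extraction is therefore
bounded by ``fu * gfr * C_p + fu * Q_pt * C_p = fu * q_renal * C_p``:
renal clearance can never exceed ``fu * q_renal`` however large the
carrier capacity. Carriers follow
Michaelis-Menten kinetics with expression scaling factors theta multiplying
Vmax: basolateral uptake (Oct2/Oat1-like, blood -> cell), apical efflux
(Mate1-like, cell -> lumen) and luminal reabsorption (Pept-like,
lumen -> central). The lumen drains to urine with first-order rate
``urine_flow_k``; non-renal elimination and zero-order endogenous synthesis
(creatinine) act on the central compartment. Endogenous analytes start at
the model steady state.

Alongside the subject simulator, this module generates complete synthetic
study datasets: two-arm plasma/urine/tissue tables with lognormal
between-subject and residual variability, qPCR Ct tables for the
delta-delta-Ct estimator, and transporter-expressing vs mock cell uptake
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .errors import IntegrationError, ValidationError
from .params import (
    CONTROL_PROFILE,
    DrugParams,
    PhysiologyParams,
    StudyDesign,
    TransporterProfile,
)

__all__ = [
    "SubjectSimulation",
    "SimulatedStudy",
    "simulate_subject",
    "simulate_study",
    "generate_qpcr",
    "generate_uptake",
]

_ROOT_XTOL = 1e-12


def _mm(vmax: float, km: float, c: float) -> float:
    if vmax == 0.0 or c <= 0.0:
        return 0.0
    return vmax * c / (km + c)


def _local_plasma_conc(cp: float, c_cell: float, phys: PhysiologyParams,
                       drug: DrugParams, theta: TransporterProfile) -> float:
    """Solve the peritubular flow balance for the local plasma concentration."""
    fu = drug.fu
    q_pt = phys.q_renal - phys.gfr  # postglomerular peritubular plasma flow
    ps = drug.ps_passive
    vup = theta.theta_uptake * drug.vmax_uptake

    def f(x: float) -> float:
        s = fu * x
        return (q_pt * fu * (cp - x)
                - _mm(vup, drug.km_uptake, s)
                - ps * (s - c_cell))

    if f(0.0) <= 0.0:
        return 0.0
    hi = cp + c_cell / fu + 1.0
    while f(hi) > 0.0:  # analytically f(hi) <= 0 already; guard roundoff
        hi *= 2.0
    return brentq(f, 0.0, hi, xtol=_ROOT_XTOL)


def _rhs(t: float, y: np.ndarray, phys: PhysiologyParams, drug: DrugParams,
         theta: TransporterProfile) -> list[float]:
    a_c, a_k, a_l = max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0)
    cp = a_c / phys.v_central
    c_cell = a_k / phys.v_kidney
    c_lum = a_l / phys.v_lumen
    fu = drug.fu

    x = _local_plasma_conc(cp, c_cell, phys, drug, theta)
    s = fu * x
    j_filt = phys.gfr * fu * cp
    j_up = _mm(theta.theta_uptake * drug.vmax_uptake, drug.km_uptake, s)
    j_pass = drug.ps_passive * (s - c_cell)
    # j_up + j_pass equals Q_pt*fu*(cp - x) by the flow balance, so total
    # extraction is capped at fu*q_renal*cp
    extraction = j_filt + j_up + j_pass
    j_eff = _mm(theta.theta_efflux * drug.vmax_efflux, drug.km_efflux, c_cell)
    j_reab = _mm(theta.theta_reab * drug.vmax_reab, drug.km_reab, c_lum)
    j_urine = phys.urine_flow_k * a_l
    j_nr = drug.cl_nonrenal * cp

    return [
        drug.synthesis_rate - j_nr - extraction + j_reab,  # central
        j_up + j_pass - j_eff,                             # tubular cell
        j_filt + j_eff - j_reab - j_urine,                 # lumen
        j_urine,                                           # urine
        j_nr,                                              # cumulative non-renal
        cp,                                                # running plasma AUC
    ]


def _steady_state(phys: PhysiologyParams, drug: DrugParams,
                  theta: TransporterProfile) -> np.ndarray:
    """Pre-dose steady state (A_c, A_k, A_l) of an endogenous analyte."""
    r = drug.synthesis_rate
    if r <= 0.0:
        return np.zeros(3)

    def resid(a):
        d = _rhs(0.0, np.array([a[0], a[1], a[2], 0.0, 0.0, 0.0]), phys, drug, theta)
        return d[:3]

    # Linearized initial guess: renal clearance ~ filtration + linear secretion.
    cl_sec = drug.fu * theta.theta_uptake * drug.vmax_uptake / drug.km_uptake \
        if drug.vmax_uptake > 0 else 0.0
    cl_r0 = min(drug.fu * phys.gfr + cl_sec, drug.fu * phys.q_renal)
    cp0 = r / max(drug.cl_nonrenal + cl_r0, 1e-12)
    j_in = cl_r0 * cp0 * 0.5
    veff = theta.theta_efflux * drug.vmax_efflux
    if veff > j_in > 0:
        c_cell0 = drug.km_efflux * j_in / (veff - j_in)
    else:
        c_cell0 = drug.km_efflux if veff > 0 else cp0
    a_l0 = cl_r0 * cp0 / phys.urine_flow_k
    guess = np.array([cp0 * phys.v_central, c_cell0 * phys.v_kidney, a_l0])

    sol = root(resid, guess, method="hybr", tol=1e-12)
    if not sol.success or np.any(sol.x < -1e-9):
        # fall back: relax toward steady state by integration, then polish
        relax = solve_ivp(_rhs, (0.0, 50000.0),
                          np.concatenate([np.clip(guess, 0, None), [0, 0, 0]]),
                          args=(phys, drug, theta), method="LSODA",
                          rtol=1e-10, atol=1e-10)
        sol = root(resid, relax.y[:3, -1], method="hybr", tol=1e-12)
    if not sol.success:
        raise IntegrationError(
            f"no steady state found for synthesis_rate={r} parameter set")
    ss = np.clip(sol.x, 0.0, None)
    scale = max(r, 1.0)
    if np.max(np.abs(resid(ss))) > 1e-7 * scale:
        raise IntegrationError("steady-state residual too large")
    return ss


@dataclass(frozen=True)
class SubjectSimulation:
    """Noiseless trajectories and sampled records of one subject."""

    times: np.ndarray            # trajectory grid, min
    a_central: np.ndarray        # nmol/kg
    a_kidney: np.ndarray
    a_lumen: np.ndarray
    a_urine: np.ndarray
    a_nonrenal: np.ndarray       # cumulative non-renal elimination
    auc_plasma: np.ndarray       # running integral of plasma conc, µM*min
    dose_nmol_per_kg: float
    synthesis_rate: float
    initial_amount: float        # total amount in system at t = 0
    sample_times: np.ndarray
    plasma_conc: np.ndarray      # µM at sample_times
    urine_intervals: tuple[tuple[float, float], ...]
    urine_amounts: np.ndarray    # nmol/kg per interval
    tissue_time: float
    tissue_conc: float           # µM

    def mass_balance_error(self) -> float:
        """Maximum relative mass-balance defect over the trajectory.

        dose + initial content + synthesized == stored + excreted + eliminated.
        """
        supplied = (self.dose_nmol_per_kg + self.initial_amount
                    + self.synthesis_rate * self.times)
        stored = (self.a_central + self.a_kidney + self.a_lumen
                  + self.a_urine + self.a_nonrenal)
        scale = max(supplied[-1], 1e-12)
        return float(np.max(np.abs(stored - supplied)) / scale)


def simulate_subject(phys: PhysiologyParams, drug: DrugParams,
                     theta: TransporterProfile = CONTROL_PROFILE,
                     design: StudyDesign | None = None,
                     t_end: float | None = None) -> SubjectSimulation:
    """Simulate one subject's noiseless disposition and sample it.

    IV bolus ``dose_mg_per_kg * 1000 / mw`` µmol/kg enters the central
    compartment at t = 0; endogenous analytes (synthesis_rate > 0, dose 0)
    start from the model steady state. Returns compartment amount
    trajectories plus plasma concentrations at ``design.sample_times``,
    urinary amounts per collection interval, and the kidney tissue
    concentration at ``design.tissue_time``.
    """
    if design is None:
        raise ValidationError("a StudyDesign is required")
    dose_nmol = design.dose_mg_per_kg * 1e6 / drug.mw
    y0 = np.zeros(6)
    y0[:3] = _steady_state(phys, drug, theta)
    initial = float(y0[:3].sum())
    y0[0] += dose_nmol

    horizon = t_end if t_end is not None else max(
        design.sample_times[-1], design.tissue_time,
        max(b for _, b in design.urine_intervals))
    interval_edges = sorted({float(e) for iv in design.urine_intervals for e in iv})
    grid = np.union1d(np.linspace(0.0, horizon, 241),
                      np.array([t for t in list(design.sample_times)
                                + interval_edges + [design.tissue_time]
                                if t <= horizon]))
    sol = solve_ivp(_rhs, (0.0, horizon), y0, t_eval=grid,
                    args=(phys, drug, theta), method="LSODA",
                    rtol=1e-8, atol=1e-10, max_step=horizon)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    y = sol.y
    scale = max(dose_nmol + initial + drug.synthesis_rate * horizon, 1.0)
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state; check parameter magnitudes")
    if np.min(y) < -1e-6 * scale:
        raise IntegrationError(
            f"negative state (min {np.min(y):.3g} nmol/kg); "
            "parameter regime is numerically unstable")
    y = np.clip(y, 0.0, None)

    def at(t_query, row):
        return np.interp(t_query, sol.t, y[row])

    sample_times = np.asarray(design.sample_times, dtype=float)
    plasma_conc = at(sample_times, 0) / phys.v_central
    urine_amounts = np.array([at(b, 3) - at(a, 3) for a, b in design.urine_intervals])
    tissue_conc = float(at(design.tissue_time, 1)) / phys.v_kidney

    return SubjectSimulation(
        times=sol.t, a_central=y[0], a_kidney=y[1], a_lumen=y[2],
        a_urine=y[3], a_nonrenal=y[4], auc_plasma=y[5],
        dose_nmol_per_kg=dose_nmol, synthesis_rate=drug.synthesis_rate,
        initial_amount=initial,
        sample_times=sample_times, plasma_conc=plasma_conc,
        urine_intervals=tuple(tuple(map(float, iv)) for iv in design.urine_intervals),
        urine_amounts=urine_amounts,
        tissue_time=float(design.tissue_time), tissue_conc=tissue_conc,
    )


def true_clearances(phys: PhysiologyParams, drug: DrugParams,
                    theta: TransporterProfile, design: StudyDesign,
                    t_inf: float = 5000.0) -> tuple[float, float]:
    """Model-implied (CL_R over the study window, CL_tot) for one parameter set.

    CL_R = urinary amount over [0, t_last] divided by the exact plasma AUC
    over the same window; CL_tot = dose / AUC to ``t_inf`` (dosed analytes
    only, NaN for endogenous ones).
    """
    t_last = max(b for _, b in design.urine_intervals)
    sim = simulate_subject(phys, drug, theta, design)
    auc_w = float(np.interp(t_last, sim.times, sim.auc_plasma)
                  - np.interp(0.0, sim.times, sim.auc_plasma))
    xu = float(np.interp(t_last, sim.times, sim.a_urine))
    cl_r = xu / auc_w if auc_w > 0 else math.nan
    if sim.dose_nmol_per_kg > 0 and drug.synthesis_rate == 0:
        ext = simulate_subject(phys, drug, theta, design, t_end=t_inf)
        cl_tot = sim.dose_nmol_per_kg / float(ext.auc_plasma[-1])
    else:
        cl_tot = math.nan
    return cl_r, cl_tot


@dataclass(frozen=True)
class SimulatedStudy:
    """Tidy tables of a simulated two-arm study plus per-subject truth."""

    plasma: pd.DataFrame
    urine: pd.DataFrame
    tissue: pd.DataFrame
    doses: pd.DataFrame
    true_params: pd.DataFrame
    seed: int


_BSV_FIELDS = ("vmax_uptake", "vmax_efflux", "vmax_reab", "cl_nonrenal")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal perturbation."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_study(phys: PhysiologyParams, drug: DrugParams,
                   theta_control: TransporterProfile,
                   theta_case: TransporterProfile,
                   design: StudyDesign,
                   analyte: str = "drug",
                   group_labels: tuple[str, str] = ("control", "hyperuricemic"),
                   compute_truth: bool = True) -> SimulatedStudy:
    """Simulate a control vs case two-arm study with noise.

    Between-subject variability multiplies the carrier Vmax terms and
    cl_nonrenal by mean-one lognormal factors (CV ``design.bsv_cv``);
    residual assay noise multiplies every sampled observation (CV
    ``design.residual_cv``). Each subject draws from an independent
    substream keyed by (master seed, arm index, subject index), so adding
    subjects or arms never reshuffles existing ones. Fully reproducible
    given ``design.seed``.
    """
    if design.n_per_group < 1:
        raise ValidationError("n_per_group must be at least 1")
    plasma_rows, urine_rows, tissue_rows, dose_rows, true_rows = [], [], [], [], []
    for arm_idx, (label, theta) in enumerate(
            zip(group_labels, (theta_control, theta_case))):
        for j in range(design.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence(design.seed, spawn_key=(arm_idx, j)))
            factors = {f: float(_lognormal_factor(rng, design.bsv_cv))
                       for f in _BSV_FIELDS}
            subj_drug = replace(drug, **{f: getattr(drug, f) * factors[f]
                                         for f in _BSV_FIELDS})
            sim = simulate_subject(phys, subj_drug, theta, design)
            sid = f"{label[:3]}{j + 1:02d}"

            conc = sim.plasma_conc * _lognormal_factor(
                rng, design.residual_cv, sim.plasma_conc.shape)
            for t, c in zip(sim.sample_times, conc):
                plasma_rows.append((sid, label, analyte, float(t), float(c)))
            amounts = sim.urine_amounts * _lognormal_factor(
                rng, design.residual_cv, sim.urine_amounts.shape)
            for (a, b), x in zip(sim.urine_intervals, amounts):
                urine_rows.append((sid, label, analyte, a, b, float(x)))
            tconc = sim.tissue_conc * float(_lognormal_factor(rng, design.residual_cv))
            tissue_rows.append((sid, label, analyte, sim.tissue_time, tconc))
            dose_rows.append((sid, analyte, design.dose_mg_per_kg, drug.mw))
            if compute_truth:
                cl_r_t, cl_tot_t = true_clearances(phys, subj_drug, theta, design)
            else:
                cl_r_t = cl_tot_t = math.nan
            true_rows.append((sid, label, analyte,
                              *[factors[f] for f in _BSV_FIELDS], cl_r_t, cl_tot_t))

    return SimulatedStudy(
        plasma=pd.DataFrame(plasma_rows, columns=[
            "subject_id", "group", "analyte", "time_min", "conc_uM"]),
        urine=pd.DataFrame(urine_rows, columns=[
            "subject_id", "group", "analyte", "t_start_min", "t_end_min",
            "amount_nmol_per_kg"]),
        tissue=pd.DataFrame(tissue_rows, columns=[
            "subject_id", "group", "analyte", "time_min", "conc_uM"]),
        doses=pd.DataFrame(dose_rows, columns=[
            "subject_id", "analyte", "dose_mg_per_kg", "mw_g_per_mol"]),
        true_params=pd.DataFrame(true_rows, columns=[
            "subject_id", "group", "analyte",
            *[f"f_{f}" for f in _BSV_FIELDS], "cl_r_true", "cl_tot_true"]),
        seed=design.seed,
    )


def generate_qpcr(true_ratios: Mapping[str, float], n_per_group: int = 6,
                  noise_sd_ct: float = 0.2, seed: int = 0,
                  reference_gene: str = "Gapdh",
                  group_labels: tuple[str, str] = ("control", "hyperuricemic"),
                  ) -> pd.DataFrame:
    """Generate a tidy Ct table whose 2^(-ddCt) estimate recovers ``true_ratios``.

    Case-group gene Ct values are shifted by -log2(ratio) cycles relative to
    control (amplification efficiency 2); independent Gaussian noise of SD
    ``noise_sd_ct`` cycles is added to every well, reference gene included.
    The ratio-to-control statistic of the expression module is consistent
    for the true ratios because the per-group multiplicative noise bias
    cancels in the ratio.
    """
    for gene, ratio in true_ratios.items():
        if not ratio > 0:
            raise ValidationError(f"expression ratio for {gene} must be > 0")
    if reference_gene in true_ratios and true_ratios[reference_gene] != 1.0:
        raise ValidationError("reference gene ratio is fixed at 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    genes = [g for g in true_ratios if g != reference_gene]
    ct_ref_base = 18.0
    rows = []
    for gi, label in enumerate(group_labels):
        for j in range(n_per_group):
            sid = f"{label[:3]}{j + 1:02d}"
            rows.append((sid, label, reference_gene,
                         ct_ref_base + rng.normal(0.0, noise_sd_ct)))
            for k, gene in enumerate(genes):
                base = ct_ref_base + 4.0 + (k % 7)  # spread targets over Ct range
                shift = 0.0 if gi == 0 else -math.log2(true_ratios[gene])
                rows.append((sid, label, gene,
                             base + shift + rng.normal(0.0, noise_sd_ct)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


def generate_uptake(mate1_component: float, background: float,
                    inhibition_fraction: Mapping[str, float], n: int = 3,
                    noise_cv: float = 0.05, seed: int = 0,
                    medium_conc_pmol_per_uL: float = 0.00025,
                    control_label: str = "control") -> pd.DataFrame:
    """Generate expressing vs mock cell uptake records for an inhibition assay.

    Mock cells carry the non-specific ``background`` cell-to-medium ratio
    (µL/mg protein); expressing cells add ``(1 - inhibition) *
    mate1_component``; both get mean-one multiplicative lognormal noise.
    A control treatment (inhibition 0) is always included.
    """
    if mate1_component < 0 or background < 0:
        raise ValidationError("uptake components must be non-negative")
    treatments = dict(inhibition_fraction)
    treatments.setdefault(control_label, 0.0)
    for name, frac in treatments.items():
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"inhibition fraction for {name} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    rows = []
    for treatment, frac in treatments.items():
        for cell_line, specific in (("expressing", (1.0 - frac) * mate1_component),
                                    ("mock", 0.0)):
            c2m = (background + specific) * _lognormal_factor(rng, noise_cv, n)
            for rep, value in enumerate(c2m, start=1):
                rows.append((cell_line, treatment, rep,
                             float(value * medium_conc_pmol_per_uL),
                             medium_conc_pmol_per_uL))
    return pd.DataFrame(rows, columns=[
        "cell_line", "treatment", "replicate",
        "amount_pmol_per_mg", "medium_conc_pmol_per_uL"])
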