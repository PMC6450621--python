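# Methods

## The mechanistic renal transport model

One simulated subject carries four mass states (amounts in nmol per kg
body weight): central plasma `A_c`, proximal tubular cells `A_k`, tubular
lumen `A_l` and urine `A_u`, plus bookkeeping integrals for cumulative
non-renal elimination and plasma AUC. Concentrations are amounts divided
by the compartment volumes (`v_central`, `v_kidney`, `v_lumen`, mL/kg), so
concentrations are in µM ≡ nmol/mL throughout.

Fluxes (nmol/min/kg):

- **Glomerular filtration** `f_u · GFR · C_p` into the lumen, at the
  systemic plasma concentration. This makes a freely filtered,
  non-transported marker's renal clearance equal GFR by construction —
  consistent with GFR being *defined* as inulin clearance.
- **Carrier secretion** draws on the postglomerular peritubular plasma
  flow `Q_pt = q_renal − GFR`. At each instant a local peritubular
  concentration `C_local` solves the algebraic flow balance
  `Q_pt·f_u·(C_p − C_local) = J_up(f_u·C_local) + PS·(f_u·C_local − C_cell)`
  by bracketed scalar root finding (Brent, xtol 1e−12; the bracket
  `[0, C_p + C_cell/f_u + 1]` provably contains the unique root because
  the balance is strictly decreasing in `C_local`). Basolateral uptake is
  Michaelis–Menten, `J_up = θ_up·Vmax_up·s/(Km_up + s)` with
  `s = f_u·C_local`, plus bidirectional passive exchange `PS`.
  Because extraction equals what the perfusing flow delivers, total renal
  extraction is bounded by `f_u·GFR·C_p + f_u·Q_pt·C_p = f_u·q_renal·C_p`:
  renal clearance can never exceed `f_u·q_renal` however large the carrier
  capacity. This is the flow-limited ("blood-flow rate-limited") regime
  relevant to metformin-like cations. Writing the balance on unbound drug
  makes the cap restrictive in f_u; the model deliberately prioritises a
  clean, provable perfusion cap over resolving the blood-vs-plasma-flow
  ambiguity inherent in whole-organ flow figures.
- **Apical efflux** (Mate1-like) `θ_eff·Vmax_eff·C_cell/(Km_eff + C_cell)`
  from cell to lumen; **luminal reabsorption** (Pept-like)
  `θ_reab·Vmax_reab·C_lum/(Km_reab + C_lum)` returned to the central
  compartment; **urine washout** first-order in luminal amount
  (`urine_flow_k`, 1/min); **non-renal clearance** `CL_nr·C_p`; zero-order
  **endogenous synthesis** into plasma for creatinine-like analytes.

The θ factors (`TransporterProfile`) scale each carrier's Vmax;
θ = 1 is control expression, θ < 1 models downregulation (e.g. 0.607 for
the observed Mate1 protein level under hyperuricemia).

**Integration.** `scipy.solve_ivp` (LSODA) with rtol 1e−8, atol 1e−10;
mass balance (dose + initial content + synthesised = stored + excreted +
eliminated) holds to < 1e−6 relative error on every tested parameter set,
and is asserted as such. Non-finite or materially negative states raise an
integration error naming the parameter regime. Endogenous analytes start
at the algebraic steady state (scipy `root` on the three disposition
states, residual < 1e−7 of the synthesis rate, with an
integrate-then-polish fallback); the simulated pre-dose concentration is
stationary to < 0.1% over 240 min.

## Default study conditions

The default design mirrors a 4-hour IV-bolus rat study: plasma samples at
5, 15, 30, 60, 120, 180, 240 min; urine pooled over 0–60, 60–120,
120–240 min (exact collection boundaries are a design choice — the study
protocol only says "designated times"); terminal kidney tissue at 240 min;
n = 3/group (larger n is used where statistical power is the point of the
check). Physiology: GFR 6.72 mL/min/kg (the measured control inulin
clearance), renal plasma flow 23 mL/min/kg (literature rat value), generic
rat-scale volumes. Kidney tissue concentration is reported as µM per mL of
tissue; no homogenate dilution factor is modelled.

Drug parameterisations (`metformin_like`, `cephalexin_like`,
`creatinine_like`, `inulin_like`) are chosen so each reproduces its
qualitative regime rather than fitted to any dataset: metformin-like has
uptake intrinsic clearance ≫ renal flow (flow-limited, CL_R ≈ f_u·Q) with
a high-capacity efflux step whose expression sets K_p; cephalexin-like
adds a saturable reabsorption carrier with small Km (3 µM) so its
clearance ratio crosses 1 between a 1 and a 10 mg/kg dose; creatinine-like
is an endogenous fu = 1 analyte whose synthesis rate (140 nmol/min/kg)
gives a steady-state plasma level near 13 µM and CL_R near 10.9 mL/min/kg.

**Variability.** Between-subject variability multiplies the three carrier
Vmax terms and CL_nr by mean-one lognormal factors (default CV 15%);
volumes and flows are fixed so the perfusion cap stays interpretable.
Residual assay noise is mean-one lognormal on every sampled observation
(default CV 10%). Randomness derives from one master seed through
`numpy.random.SeedSequence(seed, spawn_key=(arm, subject))`, so adding
subjects or arms never reshuffles existing ones, and identical seeds give
byte-identical tables.

What the generator does *not* emulate: assay limits of quantification,
time-varying GFR or flow, plasma-protein-binding kinetics beyond constant
f_u, nephron heterogeneity, and any disposition of uric acid itself.
Passing recovery tests therefore demonstrates estimator correctness under
the stated noise model, not robustness to every feature of real assay
data.

## Non-compartmental analysis

AUC uses the linear trapezoid on observed points (the log-down variant is
deliberately not used); window edges interpolate linearly, and AUC is
additive across any split at a sample time. For IV bolus data with no
measurable C(0), the window start is anchored by carrying the first
observed concentration back to t = 0 (no back-extrapolation; an explicit
choice to avoid inventing a distribution model — AUC₀₋₄ is dominated by
observed points). λz comes from log-linear OLS over candidate terminal
windows (last 3, 4, … post-peak points), selecting the highest adjusted
R², ties to fewer points — standard NCA practice; printed AUC∞ values
cannot pin the original method down. Profiles that are flat or
non-decaying raise a no-valid-fit condition and AUC∞/CL_tot are reported
as not calculable, which is how endogenous creatinine is handled.
CL_tot = D/AUC∞ and CL_R = X_urine/AUC over the window; urine interval
coverage of the window is checked and gaps are reported by span.
Molecular weights for dose conversion are configuration, not constants
(cephalexin 347.39; metformin free base 129.16 vs HCl salt 165.62 — the
salt form used for dosing is ambiguous at the few-percent level).

The clearance ratio (CL_R/f_u)/CL_inulin is classified with an ε band
(default 0.05) around 1: above → net secretion, below → net reabsorption,
within → indeterminate. Strict >1/<1 classification is available with
ε = 0; the band exists because group means at n = 3 are noisy.

Group summaries average per-animal parameters (mean ± SEM, n−1
denominator); fold changes are ratios of group means. Consistency checks
against published per-animal means therefore carry a ~3% ratio-of-means vs
mean-of-ratios allowance (e.g. D/AUC∞ from cephalexin group means gives
10.39 vs the published per-animal 10.6 mL/min/kg).

## Expression, uptake and statistics

ΔΔCt uses the control-group mean ΔCt as baseline (the per-sample vs
group-mean baseline choice is not universal; the group-mean form makes the
control mean exactly 1 after renormalisation) with amplification
efficiency fixed at 2; technical replicates average on the Ct scale. The
per-sample 2^(−ΔΔCt) is lognormally biased under Gaussian Ct noise, but
the bias is common to both groups and cancels exactly in the
ratio-to-control statistic, which is what the generator's consistency
checks exploit. Efficiency-corrected (Pfaffl-type) models are out of
scope.

Uptake reduction: cell-to-medium ratio = amount / medium concentration
(µL/mg protein); percent of control =
100·(expressing − mock)_treated / (expressing − mock)_control with
*treatment-matched* mock subtraction (the conservative reading where mock
cells are measured under every treatment), making the statistic invariant
to common additive background and common rescaling.

The default two-group test is the classic pooled-variance unpaired
Student t (df = n₁+n₂−2), with Welch as an option — the original analyses
say only "Student's t-test". Dunnett many-to-one comparisons use the
pooled-variance statistics (df = N−k−1) with the familywise adjustment
evaluated by seeded Monte-Carlo sampling of the max-|t| null (default 10⁵
draws; adjusted-p Monte-Carlo SE ≲ 0.002). This choice is
dependency-light, handles unbalanced designs, and is validated against the
k = 1 t-test reduction, an independent multivariate-t implementation, and
a 10,000-replicate null familywise-error calibration (0.05 ± 0.01).

## Numerical choices and limitations

- Root-finding and integrator tolerances are set so the mass-balance
  assertion at 1e−6 is meaningful (actual defects are ~1e−15–1e−9).
- Test and acceptance problem sizes (n = 30–50/arm for recovery and
  group-contrast checks, 10⁴ replicates for error calibration, 10⁵–4·10⁵
  Monte-Carlo draws for Dunnett) are the package's chosen balance of
  statistical resolution against runtime.
- The simulator is directional, not calibrated: parameterisations
  reproduce regimes (flow-limited secretion, saturable reabsorption,
  endogenous steady state), and absolute published values are reproduced
  only where they are pure arithmetic on published group means.
- Single-nephron/spatial tubule geometry, inter-species scaling and oral
  dosing are out of scope.
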