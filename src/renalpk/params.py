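"""Parameter containers for the mechanistic renal transport simulator.

Units follow standard small-animal PK conventions: time in minutes,
concentrations in µM (= nmol/mL), amounts in nmol per kg body weight,
volumes in mL/kg, flows and clearances in mL/min/kg, carrier maximum rates
in nmol/min/kg and affinities (Km) in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "PhysiologyParams",
    "DrugParams",
    "TransporterProfile",
    "StudyDesign",
    "RAT_PHYSIOLOGY",
    "metformin_like",
    "cephalexin_like",
    "creatinine_like",
    "inulin_like",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class PhysiologyParams:
    """Kidney/whole-body physiology of the simulated animal.

    gfr
        Glomerular filtration rate, mL/min/kg (inulin clearance).
    q_renal
        Renal plasma flow, mL/min/kg. Caps achievable renal clearance at
        fu * q_renal (flow-limited extraction of unbound drug).
    v_central
        Central (plasma + rapidly equilibrating) distribution volume, mL/kg.
    v_kidney
        Kidney tissue (tubular cell) volume, mL/kg.
    v_lumen
        Tubular luminal volume, mL/kg.
    urine_flow_k
        First-order lumen-to-urine washout rate constant, 1/min.
    """

    gfr: float
    q_renal: float
    v_central: float
    v_kidney: float
    v_lumen: float
    urine_flow_k: float

    def __post_init__(self) -> None:
        for name in ("gfr", "q_renal", "v_central", "v_kidney", "v_lumen", "urine_flow_k"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(
            self.gfr <= self.q_renal,
            f"gfr ({self.gfr}) cannot exceed renal plasma flow q_renal ({self.q_renal})",
        )


@dataclass(frozen=True)
class DrugParams:
    """Drug-specific disposition parameters.

    Carrier terms map onto the proximal-tubule transporter families:
    ``vmax_uptake/km_uptake`` a basolateral uptake carrier (Oct2/Oat1-like),
    ``vmax_efflux/km_efflux`` an apical efflux carrier (Mate1-like), and
    ``vmax_reab/km_reab`` a luminal reabsorptive carrier (Pept1/2-like).
    ``synthesis_rate`` > 0 marks an endogenous analyte (creatinine) whose
    pre-dose state is the model steady state.
    """

    mw: float
    fu: float
    cl_nonrenal: float = 0.0
    ps_passive: float = 0.0
    vmax_uptake: float = 0.0
    km_uptake: float = 1.0
    vmax_efflux: float = 0.0
    km_efflux: float = 1.0
    vmax_reab: float = 0.0
    km_reab: float = 1.0
    synthesis_rate: float = 0.0

    def __post_init__(self) -> None:
        _require(self.mw > 0, "mw must be positive")
        _require(0 < self.fu <= 1, "fu must lie in (0, 1]")
        for name in ("cl_nonrenal", "ps_passive", "vmax_uptake", "vmax_efflux",
                     "vmax_reab", "synthesis_rate"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")
        for vname, kname in (("vmax_uptake", "km_uptake"),
                             ("vmax_efflux", "km_efflux"),
                             ("vmax_reab", "km_reab")):
            if getattr(self, vname) > 0:
                _require(getattr(self, kname) > 0,
                         f"{kname} must be positive when {vname} > 0")


@dataclass(frozen=True)
class TransporterProfile:
    """Expression scaling factors multiplying the carrier Vmax terms.

    1.0 is the control expression level; hyperuricemic downregulation is
    expressed as theta < 1 (e.g. theta_efflux = 0.607 for the observed
    MATE1 protein decrease).
    """

    theta_uptake: float = 1.0
    theta_efflux: float = 1.0
    theta_reab: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_uptake", "theta_efflux", "theta_reab"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")


CONTROL_PROFILE = TransporterProfile()


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a two-arm IV-bolus disposition study."""

    dose_mg_per_kg: float
    sample_times: Sequence[float] = (5.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0)
    urine_intervals: Sequence[tuple[float, float]] = ((0.0, 60.0), (60.0, 120.0), (120.0, 240.0))
    tissue_time: float = 240.0
    n_per_group: int = 3
    bsv_cv: float = 0.15
    residual_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.dose_mg_per_kg >= 0, "dose must be non-negative")
        t = list(self.sample_times)
        _require(len(t) >= 2, "need at least two sampling times")
        _require(t[0] >= 0, "sample times must be non-negative")
        _require(all(b > a for a, b in zip(t, t[1:])), "sample times must be strictly increasing")
        ivs = sorted(tuple(map(float, iv)) for iv in self.urine_intervals)
        for (a, b) in ivs:
            _require(b > a >= 0, f"degenerate urine interval ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            _require(a1 >= b0, f"overlapping urine intervals ({a0},{b0}) and ({a1},{b1})")
        _require(self.tissue_time > 0, "tissue_time must be positive")
        _require(self.n_per_group >= 1, "n_per_group must be at least 1")
        _require(self.bsv_cv >= 0 and self.residual_cv >= 0, "CVs must be non-negative")

    def with_(self, **kwargs) -> "StudyDesign":
        return replace(self, **kwargs)


#: Control-rat physiology: GFR equals the measured control inulin clearance
#: (6.72 mL/min/kg) and renal plasma flow the literature rat value of
#: 23 mL/min/kg. Volumes are generic adult-rat scale.
RAT_PHYSIOLOGY = PhysiologyParams(
    gfr=6.72,
    q_renal=23.0,
    v_central=600.0,
    v_kidney=7.0,
    v_lumen=2.0,
    urine_flow_k=0.5,
)


def metformin_like() -> tuple[PhysiologyParams, DrugParams]:
    """Flow-limited organic cation: avid Oct2-like uptake, Mate1-like efflux.

    Uptake intrinsic clearance far exceeds renal plasma flow, so renal
    clearance sits at the fu*Q flow cap and is insensitive to efflux
    expression, while kidney accumulation is controlled by the efflux step.
    """
    phys = replace(RAT_PHYSIOLOGY, v_central=1500.0)
    drug = DrugParams(
        mw=129.16,          # metformin free base
        fu=0.85,
        cl_nonrenal=5.0,
        ps_passive=0.05,
        vmax_uptake=40000.0, km_uptake=100.0,
        vmax_efflux=6500.0, km_efflux=5000.0,
    )
    return phys, drug


def cephalexin_like() -> tuple[PhysiologyParams, DrugParams]:
    """Secreted and reabsorbed beta-lactam: Oat1/Mate1-like secretion with
    saturable Pept-like luminal reabsorption (small Km), which makes the
    clearance ratio dose-dependent."""
    phys = replace(RAT_PHYSIOLOGY, v_central=400.0)
    drug = DrugParams(
        mw=347.39,
        fu=0.82,
        cl_nonrenal=2.5,
        ps_passive=0.05,
        vmax_uptake=3000.0, km_uptake=300.0,
        vmax_efflux=6000.0, km_efflux=50.0,
        vmax_reab=55.0, km_reab=3.0,
    )
    return phys, drug


def creatinine_like() -> tuple[PhysiologyParams, DrugParams]:
    """Endogenous cation at steady state: filtration plus Oct2/Mate1-like
    secretion, no reabsorption, fu = 1."""
    phys = RAT_PHYSIOLOGY
    drug = DrugParams(
        mw=113.12,
        fu=1.0,
        cl_nonrenal=0.0,
        ps_passive=0.02,
        vmax_uptake=560.0, km_uptake=100.0,
        vmax_efflux=2000.0, km_efflux=50.0,
        synthesis_rate=140.0,
    )
    return phys, drug


def inulin_like() -> tuple[PhysiologyParams, DrugParams]:
    """Freely filtered GFR marker: no carriers, no binding, no passive flux."""
    phys = RAT_PHYSIOLOGY
    drug = DrugParams(mw=5000.0, fu=1.0)
    return phys, drug
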