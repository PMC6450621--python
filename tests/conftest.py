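import numpy as np
import pytest

import renalpk as rp
from renalpk.params import CONTROL_PROFILE


@pytest.fixture(scope="session")
def dense_design():
    """Sampling every 10 min so NCA trapezoid error is negligible."""
    return rp.StudyDesign(
        dose_mg_per_kg=100.0,
        sample_times=(2.0, *np.arange(10.0, 241.0, 10.0)),
        urine_intervals=((0.0, 60.0), (60.0, 120.0), (120.0, 240.0)),
        bsv_cv=0.0, residual_cv=0.0,
    )


@pytest.fixture(scope="session")
def filtration_only_sim(dense_design):
    """Freely filtered marker, carriers and passive flux off."""
    phys, drug = rp.inulin_like()
    return phys, drug, rp.simulate_subject(phys, drug, CONTROL_PROFILE, dense_design)


def profile_from_sim(sim, subject="s1", group="control", analyte="drug"):
    return rp.ConcentrationTimeProfile(subject, group, analyte,
                                       sim.sample_times, sim.plasma_conc)
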