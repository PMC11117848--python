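"""Shared fixtures: small plants, templates and cohorts."""

import numpy as np
import pytest

from limbsim import (
    ActivityProfile,
    PlantParameters,
    SyntheticCohortConfig,
    generate_cohort,
    make_template,
)


@pytest.fixture(scope="session")
def plant():
    """Default plant."""
    return PlantParameters()


@pytest.fixture(scope="session")
def plant_nog():
    """Plant without gravity: clean statics oracles."""
    return PlantParameters(g_m_s2=0.0)


@pytest.fixture(scope="session")
def gait_template():
    return make_template("gait")


@pytest.fixture()
def small_profile():
    """Tiny hand-made valid profile."""
    n = 11
    cyc = np.linspace(0.0, 100.0, n)
    return ActivityProfile(
        activity="gait",
        cycle_pct=cyc,
        flexion_deg=5.0 + 0.1 * cyc,
        comp_N=-(300.0 + 5.0 * cyc),
        ap_N=np.linspace(-40.0, 55.0, n),
        ie_Nm=np.linspace(0.5, 2.0, n),
        vv_Nm=np.linspace(1.0, 4.0, n),
        pelvic_rot_deg=np.sin(cyc / 18.0),
        hip_ap_mm=np.linspace(-120.0, 130.0, n),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three-patient, single-activity synthetic cohort (fast to simulate)."""
    return generate_cohort(
        SyntheticCohortConfig(n_patients=3, seed=42, activity_set=("gait",))
    )
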