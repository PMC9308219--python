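"""Shared fixtures: small simulated cohorts and reference parameters."""
import numpy as np
import pytest

from varisurv.params import PopulationParams, VisitSchedule
from varisurv.simulate import calibrate_baseline_rate, simulate_dataset


@pytest.fixture(scope="session")
def reference_params():
    """Generating parameters of the reference design, calibrated to ~80%
    censoring, with a moderate variability effect (gamma3 = 0.5)."""
    p = PopulationParams(gamma3=0.5)
    rate = calibrate_baseline_rate(p, 0.80, rng=1)
    return p.with_(baseline_hazard=rate)


@pytest.fixture(scope="session")
def small_cohort(reference_params):
    """150 subjects, semi-annual visits, 3-year lead-in (rich panels)."""
    return simulate_dataset(reference_params, VisitSchedule(3.0, 0.5),
                            150, rng=42)


@pytest.fixture(scope="session")
def short_panel_cohort(reference_params):
    """300 subjects, 1-year lead-in (short, noisy stage-1 summaries)."""
    return simulate_dataset(reference_params, VisitSchedule(1.0, 0.5),
                            300, rng=7)
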