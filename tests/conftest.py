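import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nematox.models import Species, WellOutcome

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_well(live, added=10, progeny=0, dead=0, treatment="S-0",
              species=Species.C_ELEGANS, trial="t1", well_id=None):
    return WellOutcome(
        well_id=well_id or f"w{live}-{progeny}",
        treatment_id=treatment, species=species, trial_id=trial,
        n_added=added, n_live_adults=live, n_dead=dead, n_progeny=progeny,
    )


@pytest.fixture
def spiked_treatments():
    from nematox.io import load_spiked_treatments
    return load_spiked_treatments()


@pytest.fixture
def recovery_truth():
    """Quadratic survival truth whose half-of-control crossing is 1200 µg/g.

    Decreasing over the dose grid with per-animal survival strictly inside
    (0, 1), so binomial sampling is never clamped and the fitted quadratic's
    LC50 is a consistent estimator of 1200.
    """
    b = -0.0049
    a = (4.8 - 9.6 + 0.0049 * (1200 - 59.7)) / (1200**2 - 59.7**2)
    c = 9.6 + 0.0049 * 59.7 - a * 59.7**2
    coef = (a, b, c)
    doses = (59.7, 156.0, 369.0, 1040.0, 2680.0)
    assert np.polyval(coef, 1200) == pytest.approx(4.8, abs=1e-12)
    return coef, doses
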