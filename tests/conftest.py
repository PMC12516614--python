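import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lifegain as lg

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gompertz_rates():
    """National-style Gompertz rate table over ages 50-100."""
    return lg.generate_rate_table((0.004, 0.085), (0.31, 0.23, 0.46))


@pytest.fixture(scope="session")
def reference_hazards():
    """Hazard-estimate table with a protective moderate-consumption gradient."""
    all_hr = [1.0, 0.93, 0.81, 0.87, 0.87]
    cvd_hr = [1.0, 0.90, 0.82, 0.80, 0.73]
    rows = []
    for cause, hrs, se in (("all", all_hr, 0.04), ("cvd", cvd_hr, 0.08),
                           ("cancer", [1.0] * 5, 0.08)):
        for g, h in zip(lg.GROUP_LABELS, hrs):
            rows.append(
                {"group": g, "cause": cause, "beta": np.log(h),
                 "se": 0.0 if g == "none" else se, "hr": h}
            )
    return pd.DataFrame(rows)


def make_prevalence(probs, start=20, stop=100, width=5):
    bands = np.arange(start, stop + width, width)
    prev = pd.DataFrame(
        np.tile(np.asarray(probs, float), (len(bands), 1)),
        columns=list(lg.GROUP_LABELS),
    )
    prev.insert(0, "band_lower", bands)
    prev["carried"] = False
    return prev.set_index("band_lower")


@pytest.fixture(scope="session")
def uniform_prevalence():
    return make_prevalence((0.45, 0.12, 0.17, 0.12, 0.14))


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort with exposure derived from the latent truth."""
    cohort = lg.generate_cohort(lg.SimulationConfig(n_participants=4000, seed=42))
    return lg.derive_exposure(cohort, source="true")
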