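import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest single-pair cohort with a planted interaction, reused by
    several modules' tests."""
    from fluxgei.experiments import single_pair_config
    from fluxgei.simulate import simulate_cohort

    cfg = single_pair_config(n=8000, beta_interaction=0.3, n_pcs=2, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_survival_frame(rng, n, beta, x=None, strata_labels=None):
    """Weibull PH data for direct Cox-engine checks."""
    if x is None:
        x = rng.standard_normal(n)
    eta = beta * x
    T = 95.0 * (rng.exponential(size=n) * np.exp(-eta)) ** (1 / 5)
    event = (T <= 70).astype(int)
    age = np.minimum(T, 70)
    df = pd.DataFrame({"age": age, "event": event, "x": x})
    if strata_labels is not None:
        df["stratum"] = strata_labels
    return df
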