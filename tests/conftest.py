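import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sleepdmpm.fit_bayes import MCMCConfig, fit
from sleepdmpm.synthetic_data import GeneratorConfig, generate_panel

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_panel():
    """2 subjects x 3 days with known generating parameters (enumeration-sized)."""
    return generate_panel(GeneratorConfig(n_subjects=2, n_days=3, seed=7))


@pytest.fixture(scope="session")
def small_panel():
    """50 subjects x 4 days, known parameters."""
    return generate_panel(GeneratorConfig(n_subjects=50, n_days=4, seed=3))


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """A quick 2-chain posterior on the small panel."""
    panel, _true = small_panel
    return fit(panel, mcmc=MCMCConfig(n_chains=2, n_warmup=250, n_iter=250, seed=4))


@pytest.fixture(scope="session")
def recovery_experiment():
    """The full-size recovery setting: 200 subjects x 6 days, 4x(500+500) MCMC."""
    panel, true_params = generate_panel(GeneratorConfig(n_subjects=200, n_days=6, seed=11))
    draws = fit(panel, mcmc=MCMCConfig(n_chains=4, n_warmup=500, n_iter=500, seed=5))
    return panel, true_params, draws


def true_param_values(true_params):
    """Flatten a DMPMParams into the {draw-name: true value} map."""
    from sleepdmpm.dmpm_core import CHANNELS, default_channel_specs
    from sleepdmpm.panel_data import COVARIATE_ORDER

    specs = default_channel_specs()
    out = {}
    for c in CHANNELS:
        ch = true_params.channels[c]
        if ch.family == "bernoulli-logit":
            out[f"{c}.intercept"] = ch.intercept
        else:
            out[f"{c}.cut1"], out[f"{c}.cut2"] = ch.cutpoints
        for col, v in zip(specs[c].parent_columns(), ch.beta_lag):
            out[f"{c}.lag.{col}"] = float(v)
        for cov, v in zip(COVARIATE_ORDER, ch.beta_x):
            out[f"{c}.beta.{cov}"] = float(v)
    return out


def single_draw_posterior(params):
    """Wrap fixed parameters as a one-draw posterior (oracle-parameter runs)."""
    from sleepdmpm.fit_bayes import PosteriorDraws

    values = true_param_values(params)
    return PosteriorDraws(
        draws={k: np.array([[v]]) for k, v in values.items()},
        n_chains=1, n_iter=1, seed=0,
    )
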