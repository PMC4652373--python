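import dataclasses

import numpy as np
import pytest

import ccistate as cs


@pytest.fixture(scope="session")
def truth():
    """Default synthetic truth at the full 10-year horizon."""
    return cs.default_truth()


@pytest.fixture(scope="session")
def truth_small():
    """Truth with a 2-year horizon for fast end-to-end fixtures."""
    return cs.default_truth(horizon_steps=26)


@pytest.fixture(scope="session")
def fitted_small(truth_small):
    """Generated cohort -> long format -> fitted models (shared, ~4k subjects)."""
    cohort = cs.generate_cohort(truth_small, 4000, seed=42)
    steps, report = cs.discretize_followup(cohort)
    params = cs.fit_transition_models(steps)
    return {"cohort": cohort, "steps": steps, "report": report, "params": params}


@pytest.fixture(scope="session")
def flat_params():
    """Simple parameter set with covariate-free rates: death 0.2%/step,
    change 5%/step, mean transformed size 0.3, P(>=6-type change) 10%."""
    logit = lambda p: float(np.log(p / (1 - p)))
    return cs.make_parameter_set(
        death={"intercept": logit(0.002)},
        change={"intercept": logit(0.05), "t_chg[1]": 0.4},
        size={"intercept": float(np.log(0.3))},
        ge6={"intercept": logit(0.10)},
    )


@pytest.fixture(scope="session")
def as_profile():
    return cs.Profile(treatment="AS", age_at_start=65.0, initial_cci=0)


def with_covariance(params: cs.TransitionParameterSet, sd_by_suffix: dict):
    """Copy of a parameter set with a diagonal stacked covariance, sd chosen
    by coefficient-name suffix (0 elsewhere)."""
    names = params.stacked_names
    sd = np.zeros(len(names))
    for i, nm in enumerate(names):
        for suffix, s in sd_by_suffix.items():
            if nm.endswith(suffix):
                sd[i] = s
    cov = np.diag(sd**2)
    pos = 0
    mods = {}
    for key, m in zip(("death", "change", "size", "ge6"), params.models):
        k = m.n_coefficients
        mods[key] = dataclasses.replace(m, covariance=cov[pos : pos + k, pos : pos + k])
        pos += k
    return cs.TransitionParameterSet(**mods)
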