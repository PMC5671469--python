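import numpy as np
import pandas as pd
import pytest

import gazegrid as gg
from gazegrid import glmm


@pytest.fixture(scope="session")
def grid86():
    """The default 8 x 6 grid on an 800 x 600 image."""
    return gg.build_grid(800, 600, 100, 100)


@pytest.fixture(scope="session")
def small_params():
    """A small but non-trivial generative configuration."""
    return gg.GenerativeParams(n_subjects=8, n_images=10)


@pytest.fixture(scope="session")
def small_table(small_params):
    table, truth = gg.simulate_recovery_table(small_params, seed=42)
    return table, truth


@pytest.fixture(scope="session")
def two_predictor_specs():
    maximal = gg.parse_formula(
        "fixated ~ cb_z + sal_z + (1 + cb_z + sal_z | subject) + (1 + cb_z + sal_z | image)"
    )
    zcp = gg.parse_formula(
        "fixated ~ cb_z + sal_z + (cb_z + sal_z || subject) + (cb_z + sal_z || image)"
    )
    intercept = gg.parse_formula("fixated ~ cb_z + sal_z + (1 | subject) + (1 | image)")
    return {"maximal": maximal, "zcp": zcp, "intercept": intercept}


@pytest.fixture(scope="session")
def nested_fits(small_table, two_predictor_specs):
    """Maximal / zcp / intercept-only fits of one small dataset."""
    table, _ = small_table
    return {
        name: glmm.fit(spec, table, outer_ftol=1e-8)
        for name, spec in two_predictor_specs.items()
    }


def make_dummy_fit(fixed: pd.DataFrame, **overrides) -> glmm.GLMMFit:
    """A GLMMFit shell for testing pure-arithmetic operations.

    Only the fields named in ``overrides`` (plus ``fixed``) carry
    meaningful values.
    """
    n = overrides.pop("n_obs", 100)
    defaults = dict(
        spec=gg.ModelSpec(response="fixated", random=(gg.RandomEffects("subject"),)),
        fixed=fixed,
        random_cov={},
        theta=np.array([1.0]),
        loglik=0.0,
        deviance=0.0,
        n_obs=n,
        n_params=len(fixed) + 1,
        cond_modes={},
        cond_var={},
        converged=True,
        singular=False,
        singular_flags=[],
        opt_message="dummy",
        n_outer_evals=0,
        fitted_linear=np.zeros(n),
        fitted_fixed_linear=np.zeros(n),
        fitted_mean=np.full(n, 0.5),
        random_design_var={},
        y_digest="dummy",
    )
    defaults.update(overrides)
    return glmm.GLMMFit(**defaults)
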