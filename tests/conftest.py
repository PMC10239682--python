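import numpy as np
import pytest

from emopred.game import Action
from emopred.inversion import uniform_grid_prior
from emopred.planning import PlanningConfig


@pytest.fixture(scope="session")
def cfg():
    """Default public-model planning config with a point reference marginal
    at zero (makes hand arithmetic exact)."""
    return PlanningConfig(
        lam=1.0, pi_money_values=(0.0,), pi_money_weights=(1.0,), model_variant="public"
    )


@pytest.fixture(scope="session")
def anon_cfg(cfg):
    return cfg.with_variant("anonymous")


@pytest.fixture(scope="session")
def small_prior():
    """3-point weight grids, 6-point belief grid: 4374 public support points."""
    return uniform_grid_prior("generic", n_w=3, n_pi=6)


@pytest.fixture(scope="session")
def small_base_prior():
    return uniform_grid_prior("base", n_w=3, n_pi=6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(params=[Action.C, Action.D], ids=["a1=C", "a1=D"])
def a1(request):
    return request.param
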