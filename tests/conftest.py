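import numpy as np
import pytest

from b2bsample.prior_region import Box
from b2bsample.qoi_data import load_qoi_table
from b2bsample.synthetic_model import SyntheticAlkaneModel, default_config


@pytest.fixture(scope="session")
def table():
    return load_qoi_table("default")


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def model(cfg):
    return SyntheticAlkaneModel(cfg)


@pytest.fixture(scope="session")
def design_box(cfg):
    """The standardized design box z in [-1, 1]^27 in raw parameter units."""
    return Box(cfg.x_nom - cfg.delta_ref, cfg.x_nom + cfg.delta_ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def witness_batch(model, cfg, table):
    """Masked batch sampled around a known member of the {3..8} feasible set.

    A compact cloud around an LP witness gives every test a batch with many
    members of the {3..8} intersection and a spread of partial memberships.
    """
    from b2bsample.feasibility import apply_bounds, evaluate_batch
    from b2bsample.prior_region import lhs_sample, local_box
    from b2bsample.synthetic_model import coefficient_box, lp_feasibility_oracle, solve_for_coefficients

    verdict = lp_feasibility_oracle(table, range(3, 9), coefficient_box(cfg), interior=True)
    assert verdict.feasible
    x_star = solve_for_coefficients(verdict.witness, cfg)
    box = local_box(x_star, rel=2e-3)
    X = lhs_sample(box, 4000, seed=1234)
    return apply_bounds(evaluate_batch(model, X, range(1, 21)), table)
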