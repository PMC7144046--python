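import numpy as np
import pytest

from icrsplan.synthetic import (
    CorneaParams,
    generate_cornea,
    generate_training_cohort,
)
from icrsplan import surrogate as sg


@pytest.fixture(scope="session")
def cohort100():
    """Success-filtered mechanistic cohort shared across the suite."""
    return generate_training_cohort(n_target=100, seed=101)


@pytest.fixture(scope="session")
def trained_model(cohort100):
    """Surrogate trained on 75 cases with the default hyperparameters."""
    return sg.train(cohort100[:75], seed=0)


@pytest.fixture(scope="session")
def holdout_cases(cohort100):
    return cohort100[75:]


@pytest.fixture(scope="session")
def planner_grade_surrogate():
    """Trained-to-convergence surrogate for planner validation: a 600-case
    mechanistic cohort and a two-seed committee of three-hidden-layer
    residual networks."""
    cohort = generate_training_cohort(n_target=600, seed=77)
    nets = [
        sg.train(
            cohort,
            layer_sizes=(sg.N_FEATURES, 64, 64, 64, sg.N_ZERNIKE),
            epochs=50000,
            learning_rate=0.01,
            seed=seed,
        )
        for seed in (0, 1)
    ]
    return sg.SurrogateEnsemble(nets)


@pytest.fixture(scope="session")
def kc_map():
    """One deterministic moderate keratoconic cornea."""
    return generate_cornea(CorneaParams(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_gram(max_order: int, n: int = 512) -> np.ndarray:
    """Numerical Gram matrix of the Zernike basis over the unit disk.

    Pixel-center sampling with sub-pixel area weights on the boundary ring
    (4×4 supersampling), so the quadrature error reflects the basis, not
    the jagged disk edge.
    """
    from icrsplan.zernike import zernike_basis

    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    x, y = np.meshgrid(c, c)
    r = np.hypot(x, y)
    sub = 4
    cf = (np.arange(n * sub) + 0.5) / (n * sub) * 2.0 - 1.0
    xf, yf = np.meshgrid(cf, cf)
    inside_f = (np.hypot(xf, yf) <= 1.0).reshape(n, sub, n, sub)
    w = inside_f.mean(axis=(1, 3)).ravel()
    keep = w > 0
    B = zernike_basis(max_order, r.ravel()[keep],
                      np.arctan2(y, x).ravel()[keep])
    wk = w[keep]
    return (B.T * wk) @ B / wk.sum()
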