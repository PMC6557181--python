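import numpy as np
import pytest

import reflift as rl


@pytest.fixture(scope="session")
def three_layer():
    return rl.three_layer_system()


@pytest.fixture(scope="session")
def three_layer_curves(three_layer):
    """Noise-free rendered contrast curves of the three-layer system."""
    return rl.render_contrast_series(three_layer)


@pytest.fixture(scope="session")
def d2o_curve(three_layer_curves):
    return next(c for c in three_layer_curves if c.label == "D2O")


@pytest.fixture(scope="session")
def h2o_curve(three_layer_curves):
    return next(c for c in three_layer_curves if c.label == "H2O")


@pytest.fixture(scope="session")
def truth_model(three_layer_curves):
    """The three-layer ground truth mapped onto the annealing model grid
    (D = 170 A, N = 50)."""
    D, N = 170.0, 50
    centers = (np.arange(N) + 0.5) * (D / N)
    rho = np.where(
        centers < 50, 5e-6,
        np.where(centers < 100, 0.0, np.where(centers < 150, 2e-6, 0.0)),
    )
    h = np.where(centers < 100, 0.0, np.where(centers < 150, 0.5, 1.0))
    return rl.InterfacialModel(
        D=D, rho=rho, h=h, sigma=5.0,
        q_max=max(c.q_max for c in three_layer_curves),
    )


def uniform_model(
    rho_val=3e-6, h_val=0.0, D=100.0, N=10, sigma=3.0, q_max=None, **kw
):
    return rl.InterfacialModel(
        D=D,
        rho=np.full(N, rho_val),
        h=np.full(N, h_val),
        sigma=sigma,
        q_max=q_max,
        **kw,
    )
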