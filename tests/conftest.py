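import numpy as np
import pytest

from irnet import RecurrencePlot, build_irn, scenario_params, simulate


@pytest.fixture(scope="session")
def scenario_trajectories():
    """The four damped-oscillator benchmark scenarios, simulated once."""
    return {
        name: simulate(scenario_params(name))
        for name in ("uncoupled", "x_drives_y", "y_drives_x", "bidirectional")
    }


@pytest.fixture()
def toy_irn():
    """Six-vertex toy IRN: intra-X edge v2-v3, intra-Y edge u1-u2,
    cross-edges v1-u1, v1-u2, v2-u1 (cross-degrees 2, 1, 0 on each side)."""
    eye = np.eye(3, dtype=np.uint8)
    rx = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=np.uint8)
    ry = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.uint8)
    cr = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.uint8)
    return build_irn(
        RecurrencePlot(rx + eye, "auto", 0.1, 1 / 3),
        RecurrencePlot(ry + eye, "auto", 0.1, 1 / 3),
        RecurrencePlot(cr, "cross", 0.2, 1 / 3),
    )


def random_irn(rng, n_x=None, n_y=None, p_auto=0.2, p_cross=0.15):
    """A random IRN for oracle tests (not a fixture so tests can loop it)."""
    n_x = n_x or rng.integers(2, 31)
    n_y = n_y or rng.integers(2, 31)
    rx = (rng.random((n_x, n_x)) < p_auto).astype(np.uint8)
    rx = np.triu(rx, 1)
    rx = rx + rx.T + np.eye(n_x, dtype=np.uint8)
    ry = (rng.random((n_y, n_y)) < p_auto).astype(np.uint8)
    ry = np.triu(ry, 1)
    ry = ry + ry.T + np.eye(n_y, dtype=np.uint8)
    cr = (rng.random((n_x, n_y)) < p_cross).astype(np.uint8)
    return build_irn(
        RecurrencePlot(rx, "auto", 1.0, float(p_auto)),
        RecurrencePlot(ry, "auto", 1.0, float(p_auto)),
        RecurrencePlot(cr, "cross", 1.0, float(cr.mean())),
    )
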