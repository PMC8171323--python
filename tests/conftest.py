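import numpy as np
import pytest

from photoseam.models import AnalyticDiabaticModel, make_model


class QuarticDoubleWell(AnalyticDiabaticModel):
    """1-D quartic double well V = (x^2 - 1)^2 on the lower diabat;
    the upper diabat is a distant copy so the two-state interface holds."""

    name = "quartic_double_well"
    n_states = 2
    n_coords = 1
    n_particles = 1

    def __init__(self):
        super().__init__()

    def diabatic(self, x):
        v = (x[0] ** 2 - 1.0) ** 2
        g = 4.0 * x[0] * (x[0] ** 2 - 1.0)
        H = np.array([[v, 0.0], [0.0, v + 10.0]])
        dH = np.zeros((2, 2, 1))
        dH[0, 0] = g
        dH[1, 1] = g
        return H, dH


@pytest.fixture(scope="session")
def jt_cone():
    return make_model("jt_cone")


@pytest.fixture(scope="session")
def jt_cone_tilted():
    return make_model("jt_cone", s=0.2)


@pytest.fixture(scope="session")
def jt_cone_3d():
    return make_model("jt_cone_3d")


@pytest.fixture(scope="session")
def photo():
    return make_model("two_state_photo")


@pytest.fixture(scope="session")
def cascade():
    return make_model("three_state_cascade")


@pytest.fixture(scope="session")
def cluster():
    return make_model("particle_cluster")


@pytest.fixture(scope="session")
def quartic():
    return QuarticDoubleWell()


@pytest.fixture(scope="session")
def photo_mecis(photo):
    """The two seam minima of two_state_photo, via the MECI optimizer."""
    from photoseam.selection import optimize_meci
    r1 = optimize_meci(photo, (0, 1), photo.geometry([0.83, -0.14]))
    r2 = optimize_meci(photo, (0, 1), photo.geometry([-0.48, 0.64]))
    assert r1.converged and r2.converged
    r1.meci_id, r2.meci_id = "meci_a", "meci_b"
    return r1, r2
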