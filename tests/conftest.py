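import numpy as np
import pytest

from helixpack import synthetic as syn
from helixpack.core import HelixSelector

SEL_A = HelixSelector("A", (963, 986))
SEL_B = HelixSelector("B", (692, 714))


@pytest.fixture(scope="session")
def sel_a():
    return SEL_A


@pytest.fixture(scope="session")
def sel_b():
    return SEL_B


@pytest.fixture(scope="session")
def alpha_spec():
    return syn.alpha_like_spec()


@pytest.fixture(scope="session")
def beta_spec():
    return syn.beta_like_spec()


@pytest.fixture(scope="session")
def rh_dimer(alpha_spec, beta_spec):
    """Right-handed dimer with the glycine face at the interface."""
    return syn.build_dimer(
        alpha_spec,
        beta_spec,
        syn.DimerSpec(
            omega_target=-30.0, interface_azimuth_a=200.0, interface_azimuth_b=160.0
        ),
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """Default two-mode mixture, 150 members, fixed seed."""
    return syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=150, seed=2))


def rigid_transform(rng: np.random.Generator):
    """A random proper rigid transform (R, t)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t
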