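import numpy as np
import pytest

from pbrsurf import default_liquid_set


@pytest.fixture(scope="session")
def liquids():
    return default_liquid_set()


@pytest.fixture(scope="session")
def water(liquids):
    return liquids["water"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20220101)


def random_physical_components(rng, n, liquids):
    """Component triples (gamma_lw, gamma_plus, gamma_minus) whose forward
    angle triples are strictly non-wetting for every probe liquid (theta > 0
    for all three), so the inverse problem loses no information."""
    from pbrsurf import forward_angles

    out = []
    while len(out) < n:
        comps = (
            rng.uniform(15.0, 50.0),
            rng.uniform(0.0, 8.0),
            rng.uniform(0.0, 55.0),
        )
        angles = forward_angles(comps, liquids)
        if min(angles.theta_w, angles.theta_f, angles.theta_d) < 0.5:
            continue
        out.append(comps)
    return out
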