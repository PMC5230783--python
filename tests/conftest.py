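import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from memp2rage import (
    FieldConstants,
    PhantomSpec,
    bundled_protocol,
    forward_field,
    make_phantom,
    simulate_acquisition,
)
from memp2rage.qsm import KGrid


@pytest.fixture(scope="session")
def me_protocol():
    return bundled_protocol("me_mp2rage")


@pytest.fixture(scope="session")
def mp_protocol():
    return bundled_protocol("mp2rage")


@pytest.fixture(scope="session")
def mp_sim_protocol():
    return bundled_protocol("mp2rage_sim")


@pytest.fixture(scope="session")
def flash_protocol():
    return bundled_protocol("me_flash")


@pytest.fixture(scope="session")
def inversion_protocols(me_protocol, mp_protocol, mp_sim_protocol):
    return {"me_mp2rage": me_protocol, "mp2rage": mp_protocol,
            "mp2rage_sim": mp_sim_protocol}


@pytest.fixture(scope="session")
def phantom_truth():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_acq(phantom_truth, me_protocol):
    return simulate_acquisition(phantom_truth, me_protocol, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def blob_chi():
    """Smooth Gaussian-blob susceptibility phantom, sources compactly
    inside a spherical mask, plus its exact forward dipole field."""
    shape = (64, 64, 64)
    kg = KGrid(shape, (0.6, 0.6, 0.6))
    grids = np.meshgrid(*[np.arange(n) - n / 2 + 0.5 for n in shape],
                        indexing="ij", sparse=True)
    mask = sum(g**2 for g in grids) <= 26**2
    rng = np.random.default_rng(1)
    chi = np.zeros(shape)
    for _ in range(6):
        c = rng.uniform(-6, 6, 3)
        w = rng.uniform(2.0, 4.0)
        a = rng.uniform(-50, 80)
        r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        chi += a * np.exp(-r2 / (2 * w**2))
    field = forward_field(chi, kg)
    return {"chi": chi, "field": field, "mask": mask, "kg": kg,
            "fc": FieldConstants()}


def masked_regression(truth, recovered, mask):
    """Slope and r^2 of recovered vs (mean-centred) truth over a mask."""
    x = truth[mask] - truth[mask].mean()
    y = recovered[mask] - recovered[mask].mean()
    slope = float(np.polyfit(x, y, 1)[0])
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return slope, r2
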