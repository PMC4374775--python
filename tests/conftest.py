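import numpy as np
import pytest

from pkmech.designs import (
    ADPMG_LEVELS_MM,
    INHIBITION_DESIGNS,
    PEP_LEVELS_MM,
    TPPK_MG_PARAMS,
)
from pkmech.rate_laws import InhibitionParams
from pkmech.synthetic import NoiseModel, make_velocity_dataset


@pytest.fixture
def velocity_grid():
    """The published bisubstrate concentration grid (PEP3- x ADP-Mg)."""
    return {"a_levels": PEP_LEVELS_MM, "b_levels": ADPMG_LEVELS_MM}


@pytest.fixture
def noiseless_random_re(velocity_grid):
    return make_velocity_dataset("random_re", TPPK_MG_PARAMS, velocity_grid)


def inhibition_design(key):
    d = INHIBITION_DESIGNS[key]
    return {
        "s_levels": d["substrate_mM"],
        "i_levels": d["inhibitor_mM"],
        "fixed_cosubstrate": d["fixed_cosubstrate_mM"],
    }


@pytest.fixture
def noiseless_oxalate_competitive():
    params = InhibitionParams(v=183.0, km=0.38, ki=0.05, kind="competitive")
    return make_velocity_dataset(
        "competitive", params, inhibition_design("oxalate_vs_pep")
    )


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
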