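"""Shared fixtures: deterministic RNGs and cached simulation ensembles."""

import numpy as np
import pytest

from tangentchain.conformation import Conformation
from tangentchain.mc import SquareWellModel, run_infinite_temperature
from tangentchain.pipeline import low_temperature_ensemble
from tangentchain.synthetic import HelixParams, ideal_alpha_helix, ideal_beta_sheet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix30():
    return ideal_alpha_helix(HelixParams(n=30))


@pytest.fixture(scope="session")
def antiparallel_sheet():
    return ideal_beta_sheet()


@pytest.fixture(scope="session")
def infinite_T_ensemble():
    """Equilibrated self-avoiding 80-bead chains at infinite temperature."""
    model = SquareWellModel(n=80)
    samples = run_infinite_temperature(model, 2000, seed=7, sample_stride=10, burn_in=2000)
    return [Conformation(c, bond_length=model.sigma) for c in samples]


@pytest.fixture(scope="session")
def low_T_run():
    """Replica-exchange snapshots at reduced T = 0.3 plus the energy traces."""
    confs, trace = low_temperature_ensemble(1500, seed=42, sweeps_per_snapshot=10)
    return confs, trace
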