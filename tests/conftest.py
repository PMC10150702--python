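"""Shared fixtures: default model parameters and small preprocessed volumes."""

import dataclasses

import numpy as np
import pytest

from octmargin.params import (
    CohortSpec,
    TissueLabel,
    default_system,
    default_tissue_params,
)
from octmargin.preprocess import (
    compensate_depth,
    detect_surface,
    normalize_surface,
)
from octmargin.simulate import simulate_volume


@pytest.fixture(scope="session")
def system():
    return default_system()

@pytest.fixture(scope="session")
def quiet_system(system):
    """Flat sensitivity and negligible noise floor, for exact identities."""
    flat = system.with_flat_profiles()
    return dataclasses.replace(flat, noise_floor_db=-300.0)


@pytest.fixture(scope="session")
def tissue_params():
    return default_tissue_params()


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_patients=4, scans_per_patient=2, bscans_per_subvolume=8, seed=7
    )


def preprocess_volume(volume, system):
    """Compensate + surface-normalize one raw volume."""
    comp = compensate_depth(volume, system)
    surface = detect_surface(comp, noise_floor_db=system.noise_floor_db)
    return normalize_surface(comp, surface, noise_floor_db=system.noise_floor_db)


@pytest.fixture(scope="session")
def normalized_volume_factory(system, tissue_params):
    """Simulate + preprocess a small subvolume of a given class, seeded."""

    def factory(label: TissueLabel, n_bscans: int = 10, seed: int = 0):
        rng = np.random.default_rng(seed)
        volume, truth = simulate_volume(tissue_params[label], system, n_bscans, rng)
        return preprocess_volume(volume, system), truth

    return factory
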