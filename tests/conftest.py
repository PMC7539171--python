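from __future__ import annotations

import pytest

from cin_ephys.synth import (
    GroupSpec,
    CohortSpec,
    make_fs_and_nonfs_presets,
    simulate_cell,
)


@pytest.fixture(scope="session")
def presets():
    return make_fs_and_nonfs_presets()


@pytest.fixture(scope="session")
def fs_cell():
    """Noiseless mean fast-spiking cell: (protocol, ground truth)."""
    fs, _ = make_fs_and_nonfs_presets()
    return simulate_cell(fs.mean_cell(), cell_id="fs_mean", noise_sd=0.0,
                         seed=1)


@pytest.fixture(scope="session")
def noisy_fs_cell():
    """Mean FS cell at 0.2 mV band-limited noise."""
    fs, _ = make_fs_and_nonfs_presets()
    return simulate_cell(fs.mean_cell(), cell_id="fs_noisy", noise_sd=0.2,
                         seed=7)


@pytest.fixture(scope="session")
def nonfs_cell():
    """Noiseless mean adapting (non-FS) cell."""
    _, nonfs = make_fs_and_nonfs_presets()
    return simulate_cell(nonfs.mean_cell(), cell_id="nonfs_mean",
                         noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """2 groups × 2 animals × 2 cells at modest noise (pipeline tests)."""
    fs, nonfs = make_fs_and_nonfs_presets()
    groups = {
        "A": GroupSpec(n_animals=2, cells_per_animal=2, fraction_fs=0.5,
                       fs=fs, nonfs=nonfs),
        "B": GroupSpec(n_animals=2, cells_per_animal=2, fraction_fs=0.5,
                       fs=fs, nonfs=nonfs),
    }
    return CohortSpec(groups=groups, seed=11, noise_sd=0.1)
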