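import numpy as np
import pandas as pd
import pytest

from isomerge.reflio import OBS_COLUMNS, UnitCell, UnmergedDataset
from isomerge.synthgen import SimulationConfig, simulate_group_set


def make_dataset(
    serial=1,
    cell=(40.0, 50.0, 60.0, 90.0, 90.0, 90.0),
    spacegroup="P 1",
    n_images=10,
    obs=None,
    dataset_id=None,
):
    """Small hand-rolled dataset for unit tests."""
    if obs is None:
        rng = np.random.default_rng(serial)
        n = 50
        hkl = rng.integers(-5, 6, size=(n, 3))
        hkl[(hkl == 0).all(axis=1)] = [1, 0, 0]
        obs = pd.DataFrame(
            {
                "h": hkl[:, 0],
                "k": hkl[:, 1],
                "l": hkl[:, 2],
                "intensity": rng.exponential(100.0, n),
                "sigma": rng.uniform(1.0, 5.0, n),
                "image": rng.integers(1, n_images + 1, n),
            }
        )
    return UnmergedDataset(
        dataset_id=dataset_id or f"test{serial:02d}",
        serial=serial,
        cell=UnitCell(*cell),
        spacegroup=spacegroup,
        first_image=1,
        last_image=n_images,
        observations=obs[OBS_COLUMNS],
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def two_group_sim():
    """The clean two-group condition: 2 A shift on edge a, 0.05 A jitter."""
    cfg = SimulationConfig(
        n_groups=2,
        group_shift=2.0,
        cell_jitter=0.05,
        n_per_group=5,
        d_min=3.0,
        wedge_images=20,
        obs_per_image=40,
        noise_frac=0.0,
        background_sigma=1e-6,
        seed=101,
    )
    return simulate_group_set(cfg)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory):
    """Factory for on-disk scenarios, cached per (name, seed)."""
    from isomerge.synthgen import make_scenario

    cache = {}

    def _get(name, seed=0):
        key = (name, seed)
        if key not in cache:
            outdir = tmp_path_factory.mktemp(f"{name}_{seed}")
            cache[key] = (outdir, *make_scenario(name, outdir, seed=seed))
        return cache[key]

    return _get
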