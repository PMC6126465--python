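"""Synthetic multi-crystal unmerged datasets with known ground truth.

Stands in for real multi-wedge collections: groups of crystals with small
within-group and larger between-group cell perturbations, short contiguous
rotation wedges, per-dataset scale factors, per-image radiation-damage decay
and counting-type noise.  True unique intensities follow an acentric Wilson
(exponential) distribution whose mean carries the Debye-Waller factor
exp(-2 * B_wilson * (sin theta / lambda)^2) = exp(-B_wilson * s / 2) with
B_wilson = 20 A^2 and s = 1/d^2.

Two damage channels are modelled:

* ``damage_B`` (A^2 per image) — a B factor growing linearly with image
  number, I *= exp(-2 * damage_B * (image - first) * s).  The decay is
  faster at high resolution, which is what the damage detector tests for.
* ``uniform_decay`` (per image) — resolution-independent decay,
  I *= exp(-uniform_decay * (image - first)), emulating bulk intensity loss
  that the resolution-trend test deliberately does not flag; image pruning
  is the remedy for this channel.

No diffraction geometry is simulated: each image samples reflections from a
shuffled cycle through the unique list, so long sweeps cover the unique set
multiply while short wedges stay partial.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reflio import UnitCell, UnmergedDataset, write_dataset
from .scalemerge import SymmetryOps, _encode, map_to_unique

__all__ = [
    "SimulationConfig",
    "ground_truth",
    "simulate_dataset",
    "simulate_group_set",
    "make_scenario",
    "SCENARIOS",
]

B_WILSON = 20.0  # A^2, overall Wilson B of the true intensities


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-crystal collection.

    ``group_shift`` moves edge a between crystal groups; ``cell_jitter`` is
    the within-group sd on all three edges.  ``n_per_group`` may be an int or
    a per-group tuple.  ``full_sweep`` extends every sweep far enough to
    cover the unique set at least once.  ``rogue_ids`` (serials or dataset
    ids) receive per-image log-normal scale errors no smooth scale model can
    absorb.
    """

    base_cell: tuple = (40.0, 50.0, 60.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P 21 21 21"
    n_groups: int = 1
    group_shift: float = 2.0            # A added to edge a per group
    cell_jitter: float = 0.05           # A sd of per-dataset edge jitter
    n_per_group: int | tuple = 5
    d_min: float = 3.0
    wedge_images: int = 30              # images per dataset (extra images if full_sweep)
    full_sweep: bool = False
    obs_per_image: int = 40
    scale_k_range: tuple = (0.5, 2.0)
    scale_B_range: tuple = (0.0, 10.0)
    damage_B_range: tuple = (0.0, 0.0)       # A^2/image, resolution-dependent decay
    uniform_decay_range: tuple = (0.0, 0.0)  # 1/image, resolution-independent
    noise_frac: float = 0.05
    background_sigma: float = 1.0
    n_outliers: int = 0
    outlier_shift: float = 20.0         # A shift on edge a for outlier cells
    rogue_ids: tuple = ()
    rogue_scale_error: float = 0.5
    seed: int = 0

    def group_sizes(self) -> list[int]:
        if isinstance(self.n_per_group, int):
            return [self.n_per_group] * self.n_groups
        if len(self.n_per_group) != self.n_groups:
            raise ValueError("n_per_group tuple must have n_groups entries")
        return list(self.n_per_group)


def _rng(config: SimulationConfig, *streams: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *streams])


def ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """True unique intensities of the base cell to d_min (Wilson statistics)."""
    cell = UnitCell(*config.base_cell)
    ops = SymmetryOps.from_symbol(config.spacegroup)
    hmax = int(math.ceil(cell.a / config.d_min)) + 1
    kmax = int(math.ceil(cell.b / config.d_min)) + 1
    lmax = int(math.ceil(cell.c / config.d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[(hkl != 0).any(axis=1)]
    s_all = cell.inv_d2(hkl)
    keep = s_all <= 1.0 / config.d_min**2 + 1e-9
    keys = map_to_unique(hkl[keep], ops)
    code = _encode(keys)
    _uniq, idx = np.unique(code, return_index=True)
    keys = keys[idx]
    s_u = s_all[keep][idx]
    rng = _rng(config, 1)
    mean = 1000.0 * np.exp(-B_WILSON * s_u / 2.0)
    intensities = rng.exponential(mean)
    return pd.DataFrame(
        {
            "h": keys[:, 0],
            "k": keys[:, 1],
            "l": keys[:, 2],
            "s": s_u,
            "intensity": intensities,
        }
    )


def _dataset_cell(config: SimulationConfig, group: int, index: int, outlier: bool) -> UnitCell:
    rng = _rng(config, 2, group, index)
    a, b, c, al, be, ga = config.base_cell
    a += group * config.group_shift
    if outlier:
        a += config.outlier_shift
    jit = rng.normal(0.0, config.cell_jitter, size=3)
    return UnitCell(a + jit[0], b + jit[1], c + jit[2], al, be, ga)


def simulate_dataset(
    config: SimulationConfig,
    truth: pd.DataFrame,
    group: int,
    index: int,
    serial: int,
    outlier: bool = False,
) -> tuple[UnmergedDataset, dict]:
    """One crystal's wedge: cell perturbation, scales, damage, noise.

    Observed I = k * exp(-2*B*s) * exp(-2*damage_B*dose*s)
               * exp(-uniform_decay*dose) * I_true + Gaussian noise with
    sigma = sqrt((noise_frac * I)^2 + background_sigma^2); dose = image - 1.
    Returns the dataset and its ground-truth parameter record.
    """
    rng = _rng(config, 3, group, index)
    dataset_id = f"group{group}_crystal{index:02d}"
    cell = _dataset_cell(config, group, index, outlier)
    k_true = rng.uniform(*config.scale_k_range)
    B_true = rng.uniform(*config.scale_B_range)
    damage_B = rng.uniform(*config.damage_B_range)
    uniform_decay = rng.uniform(*config.uniform_decay_range)
    rogue = dataset_id in config.rogue_ids or serial in config.rogue_ids
    n_unique = len(truth)
    if config.full_sweep:
        n_images = int(math.ceil(n_unique / config.obs_per_image)) + config.wedge_images
    else:
        n_images = config.wedge_images
    need = n_images * config.obs_per_image
    reps = int(math.ceil(need / n_unique))
    stream = np.concatenate([rng.permutation(n_unique) for _ in range(reps)])
    picks = stream[:need]                       # (n_images * obs_per_image,)
    image = np.repeat(np.arange(1, n_images + 1), config.obs_per_image)
    dose = (image - 1).astype(float)
    hkl_picks = truth[["h", "k", "l"]].to_numpy()[picks]
    # resolution follows the crystal's own (perturbed) cell geometry
    s = cell.inv_d2(hkl_picks)
    i_true = truth["intensity"].to_numpy()[picks]
    per_image_scale = np.ones(n_images)
    if rogue:
        per_image_scale = np.exp(rng.normal(0.0, config.rogue_scale_error, size=n_images))
    signal = (
        k_true
        * np.exp(-2.0 * B_true * s)
        * np.exp(-2.0 * damage_B * dose * s)
        * np.exp(-uniform_decay * dose)
        * per_image_scale[image - 1]
        * i_true
    )
    sigma = np.sqrt((config.noise_frac * signal) ** 2 + config.background_sigma**2)
    observed = signal + rng.normal(0.0, sigma)
    obs = pd.DataFrame(
        {
            "h": hkl_picks[:, 0],
            "k": hkl_picks[:, 1],
            "l": hkl_picks[:, 2],
            "intensity": observed,
            "sigma": sigma,
            "image": image,
        }
    )
    ds = UnmergedDataset(
        dataset_id=dataset_id,
        serial=serial,
        cell=cell,
        spacegroup=config.spacegroup,
        first_image=1,
        last_image=n_images,
        observations=obs,
    )
    record = {
        "dataset_id": dataset_id,
        "group": group,
        "outlier": bool(outlier),
        "rogue": bool(rogue),
        "cell": list(cell.as_tuple()),
        "k": k_true,
        "B": B_true,
        "damage_B": damage_B,
        "uniform_decay": uniform_decay,
        "n_images": n_images,
    }
    return ds, record


def simulate_group_set(config: SimulationConfig) -> tuple[list[UnmergedDataset], list[dict]]:
    """All datasets of a configuration: the group members plus any outliers."""
    truth = ground_truth(config)
    datasets, records = [], []
    serial = 0
    for g, size in enumerate(config.group_sizes()):
        for i in range(size):
            serial += 1
            ds, rec = simulate_dataset(config, truth, g, i, serial)
            datasets.append(ds)
            records.append(rec)
    for i in range(config.n_outliers):
        serial += 1
        ds, rec = simulate_dataset(config, truth, config.n_groups, i, serial, outlier=True)
        ds.dataset_id = f"outlier_crystal{i:02d}"
        rec["dataset_id"] = ds.dataset_id
        datasets.append(ds)
        records.append(rec)
    return datasets, records


def _scenario_config(name: str, seed: int) -> SimulationConfig:
    if name == "teha_like":
        # 63 isomorphous short wedges in two slightly offset subgroups with
        # detectable (resolution-dependent) damage, plus 4 gross outliers
        return SimulationConfig(
            n_groups=2,
            group_shift=0.35,
            cell_jitter=0.05,
            n_per_group=(32, 31),
            d_min=3.0,
            wedge_images=30,
            obs_per_image=100,
            damage_B_range=(0.08, 0.2),
            noise_frac=0.05,
            background_sigma=25.0,
            n_outliers=4,
            outlier_shift=25.0,
            seed=seed,
        )
    if name == "h1r_like":
        # 18 long-sweep datasets in 3 loose groups with resolution-
        # independent decay (the trend test finds nothing; pruning helps);
        # the groups are far enough apart that only within-group nodes
        # stay under a few Angstrom of aLCV
        return SimulationConfig(
            n_groups=3,
            group_shift=5.0,
            cell_jitter=0.15,
            n_per_group=6,
            d_min=3.0,
            wedge_images=10,
            full_sweep=True,
            obs_per_image=60,
            uniform_decay_range=(0.01, 0.03),
            noise_frac=0.08,
            seed=seed,
        )
    if name == "two_group":
        # clean two-group separation for clustering and noiseless scale recovery
        return SimulationConfig(
            n_groups=2,
            group_shift=2.0,
            cell_jitter=0.05,
            n_per_group=5,
            d_min=3.0,
            wedge_images=20,
            obs_per_image=40,
            noise_frac=0.0,
            background_sigma=1e-6,
            seed=seed,
        )
    if name == "rogue":
        # one cluster with a planted mis-scaled dataset (per-image scale jitter)
        return SimulationConfig(
            n_groups=1,
            n_per_group=5,
            cell_jitter=0.05,
            d_min=3.0,
            wedge_images=15,
            full_sweep=True,
            obs_per_image=50,
            noise_frac=0.05,
            rogue_ids=(3,),
            rogue_scale_error=0.8,
            seed=seed,
        )
    if name == "damaged":
        # highly redundant full sweeps with strong uniform tail decay
        return SimulationConfig(
            n_groups=1,
            n_per_group=4,
            cell_jitter=0.05,
            d_min=3.0,
            wedge_images=20,
            full_sweep=True,
            obs_per_image=50,
            uniform_decay_range=(0.03, 0.05),
            noise_frac=0.05,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("teha_like", "h1r_like", "two_group", "rogue", "damaged")


def make_scenario(
    name: str, outdir: str | os.PathLike, seed: int = 0
) -> tuple[list[UnmergedDataset], dict]:
    """Write a named scenario as canonical files + a ground-truth manifest.

    Returns (datasets, manifest).  The manifest records every ground-truth
    parameter (per-dataset cell, scales, damage rates, group labels) for
    recovery tests.  Regeneration with the same seed is bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = _scenario_config(name, seed)
    datasets, records = simulate_group_set(config)
    for ds in datasets:
        path = outdir / f"{ds.dataset_id}.refl"
        write_dataset(ds, path)
        ds.source_path = str(path)
    manifest = {
        "scenario": name,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "datasets": records,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return datasets, manifest
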