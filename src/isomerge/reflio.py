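"""Canonical data model and readers/writers for unmerged reflection datasets.

The canonical dialect is a self-describing plain-text format: a small header
block (CELL, SPACEGROUP, IMAGES) followed by an observation table with columns
H K L I SIGI IMAGE.  Adapters for XDS INTEGRATE.HKL and unmerged MTZ expose
the same :class:`UnmergedDataset` contract.

Conventions: images are 1-based inclusive; resolution d is in Angstrom and
s = 1/d**2 is the internal resolution coordinate.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "Observation",
    "UnmergedDataset",
    "FinalListEntry",
    "KeywordSet",
    "FormatError",
    "read_dataset",
    "write_dataset",
    "gather_inputs",
    "write_final_list",
    "read_final_list",
    "OBS_COLUMNS",
]

OBS_COLUMNS = ["h", "k", "l", "intensity", "sigma", "image"]

CANONICAL_EXTENSIONS = (".refl", ".txt", ".dat", ".hkl", ".mtz")


class FormatError(ValueError):
    """Raised when an input reflection file cannot be parsed."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters a, b, c (Angstrom) and alpha, beta, gamma (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell edge {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        # positive-definite metric tensor; also rejects impossible angle triples
        try:
            np.linalg.cholesky(self.metric_tensor())
        except np.linalg.LinAlgError:
            raise ValueError("cell parameters give a non-positive-definite metric")

    def metric_tensor(self) -> np.ndarray:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    def inv_d2(self, hkl: np.ndarray) -> np.ndarray:
        """s = 1/d**2 for an (n, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        g = self.reciprocal_metric()
        return np.einsum("ni,ij,nj->n", hkl, g, hkl)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        return 1.0 / np.sqrt(self.inv_d2(hkl))

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class Observation:
    """One integrated reflection observation."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    image: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("Miller index (0,0,0) is not a reflection")


@dataclass
class UnmergedDataset:
    """One crystal's cell, symmetry, image range and observation table.

    ``observations`` is a DataFrame with columns h, k, l, intensity, sigma,
    image (the list-of-Observation view is available via :meth:`observation_list`).
    """

    dataset_id: str
    serial: int
    cell: UnitCell
    spacegroup: str
    first_image: int
    last_image: int
    observations: pd.DataFrame
    source_path: str = ""

    def __post_init__(self):
        if self.serial < 1:
            raise ValueError("serial must be a positive integer")
        if self.first_image > self.last_image:
            raise ValueError("first_image must be <= last_image")
        obs = self.observations
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if len(obs):
            img = obs["image"].to_numpy()
            if img.min() < self.first_image or img.max() > self.last_image:
                bad = int(img[(img < self.first_image) | (img > self.last_image)][0])
                raise ValueError(
                    f"observation cites image {bad} outside range "
                    f"[{self.first_image}, {self.last_image}]"
                )
            if (obs["sigma"].to_numpy() <= 0).any():
                raise ValueError("all sigmas must be > 0")
            if ((obs[["h", "k", "l"]].to_numpy() == 0).all(axis=1)).any():
                raise ValueError("Miller index (0,0,0) present")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_images(self) -> int:
        return self.last_image - self.first_image + 1

    def hkl(self) -> np.ndarray:
        return self.observations[["h", "k", "l"]].to_numpy(dtype=int)

    def inv_d2(self) -> np.ndarray:
        """s = 1/d**2 of every observation."""
        return self.cell.inv_d2(self.hkl())

    def d_min(self) -> float:
        """Resolution of the most extreme observed reflection (Angstrom)."""
        return float(1.0 / math.sqrt(self.inv_d2().max()))

    def observation_list(self) -> list[Observation]:
        return [
            Observation(int(r.h), int(r.k), int(r.l), float(r.intensity), float(r.sigma), int(r.image))
            for r in self.observations.itertuples()
        ]

    def truncated(self, first: int | None = None, last: int | None = None) -> "UnmergedDataset":
        """Copy restricted to images in [first, last] (range intersected)."""
        lo = max(self.first_image, first if first is not None else self.first_image)
        hi = min(self.last_image, last if last is not None else self.last_image)
        if lo > hi:
            raise ValueError("empty image range after truncation")
        obs = self.observations
        keep = obs[(obs["image"] >= lo) & (obs["image"] <= hi)].reset_index(drop=True)
        return replace(self, first_image=lo, last_image=hi, observations=keep)


@dataclass
class FinalListEntry:
    """One row of the six-column per-dataset summary list.

    Columns: path, serial, cutoff image (last accepted image; equal to
    last_image when no pruning is suggested), first image, last image,
    suggested resolution in Angstrom.
    """

    path: str
    serial: int
    cutoff_image: int | None
    first_image: int
    last_image: int
    suggested_resolution: float

    def __post_init__(self):
        if self.cutoff_image is not None and not (
            self.first_image <= self.cutoff_image <= self.last_image
        ):
            raise ValueError("cutoff_image outside image range")
        if not self.suggested_resolution > 0:
            raise ValueError("suggested_resolution must be > 0")

    @property
    def effective_cutoff(self) -> int:
        return self.cutoff_image if self.cutoff_image is not None else self.last_image


@dataclass
class KeywordSet:
    """Run configuration, read from a plain-text keyword stream.

    Defaults: ISIGI 1.5 (signal/noise threshold for the resolution estimate),
    RADFRAC 0.75 (intensity fraction defining the damage cutoff image),
    TOLERANCE 2 (max % cell-edge / degree angle discrepancy allowed when
    merging), COMPLETENESS 95 (pruning target, percent).
    """

    resolution_high: float | None = None
    resolution_low: float | None = None
    radfrac: float = 0.75
    isigi: float = 1.5
    tolerance: float = 2.0
    completeness_target: float = 95.0
    max_prune_cycles: int = 20
    prune_fraction: float = 0.10
    seed: int = 42

    def __post_init__(self):
        if not 0 < self.radfrac <= 1:
            raise ValueError("radfrac must be in (0, 1]")
        if not self.isigi > 0:
            raise ValueError("isigi must be > 0")
        if not 0 < self.completeness_target <= 100:
            raise ValueError("completeness_target must be in (0, 100]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


# ---------------------------------------------------------------------------
# canonical dialect


def write_dataset(ds: UnmergedDataset, path: str | os.PathLike) -> None:
    """Write a dataset in the canonical text dialect."""
    path = Path(path)
    c = ds.cell
    # shortest-roundtrip float formatting keeps write/read an exact identity
    cellvals = " ".join(repr(float(v)) for v in c.as_tuple())
    with open(path, "w") as fh:
        fh.write(f"DATASET {ds.dataset_id}\n")
        fh.write(f"CELL {cellvals}\n")
        fh.write(f"SPACEGROUP {ds.spacegroup}\n")
        fh.write(f"IMAGES {ds.first_image} {ds.last_image}\n")
        fh.write("H K L I SIGI IMAGE\n")
        for r in ds.observations.itertuples():
            fh.write(
                f"{int(r.h)} {int(r.k)} {int(r.l)} "
                f"{float(r.intensity)!r} {float(r.sigma)!r} {int(r.image)}\n"
            )


def _read_canonical(path: Path) -> UnmergedDataset:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not in_table:
                key = line.split()[0].upper()
                if key == "H" and line.upper().split() == ["H", "K", "L", "I", "SIGI", "IMAGE"]:
                    in_table = True
                    continue
                header[key] = line[len(line.split()[0]):].strip()
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    for req in ("CELL", "SPACEGROUP", "IMAGES"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req}")
    try:
        cellvals = [float(x) for x in header["CELL"].split()]
        if len(cellvals) != 6:
            raise ValueError("CELL needs 6 numbers")
        cell = UnitCell(*cellvals)
    except ValueError as exc:
        raise FormatError(f"{path}: bad CELL header: {exc}") from None
    try:
        first, last = (int(x) for x in header["IMAGES"].split())
    except ValueError:
        raise FormatError(f"{path}: bad IMAGES header: {header['IMAGES']!r}") from None
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS) if rows else pd.DataFrame(columns=OBS_COLUMNS)
    if len(obs):
        obs = obs.astype({"h": int, "k": int, "l": int, "image": int})
    return UnmergedDataset(
        dataset_id=header.get("DATASET", path.stem),
        serial=1,
        cell=cell,
        spacegroup=header["SPACEGROUP"],
        first_image=first,
        last_image=last,
        observations=obs,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# XDS INTEGRATE.HKL dialect


def _read_xds_integrate(path: Path) -> UnmergedDataset:
    """Read an XDS INTEGRATE.HKL-style file.

    Column layout is taken from the !ITEM_ header records when present,
    otherwise the stock INTEGRATE.HKL order (H K L IOBS SIGMA ... ZCAL at
    column 8) is assumed.  The image number is floor(ZCAL) + 1.  Indices are
    reported in P1 regardless of the header's space-group number: intensities
    at the integration stage describe a structure without symmetry, and
    symmetry is applied downstream.
    """
    cell = None
    first = last = None
    items: dict[str, int] = {}
    scaled_marker = False
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!"):
                up = line.upper()
                if "UNIT_CELL_CONSTANTS=" in up:
                    vals = [float(x) for x in up.split("=", 1)[1].split()[:6]]
                    cell = UnitCell(*vals)
                elif "DATA_RANGE=" in up:
                    first, last = (int(float(x)) for x in up.split("=", 1)[1].split()[:2])
                elif up.startswith("!ITEM_"):
                    name = up[len("!ITEM_"):].split("=")[0].strip()
                    items[name] = int(up.split("=", 1)[1]) - 1
                elif "XDS_ASCII" in up or "CORRECT" in up:
                    scaled_marker = True
                continue
            if not line.strip():
                continue
            rows.append([float(x) for x in line.split()])
    if cell is None:
        raise FormatError(f"{path}: missing UNIT_CELL_CONSTANTS header")
    if first is None:
        raise FormatError(f"{path}: missing DATA_RANGE header")
    if scaled_marker:
        warnings.warn(
            f"{path}: header suggests post-CORRECT (scaled) data; "
            "integration-stage intensities are recommended",
            UserWarning,
            stacklevel=3,
        )
    ih = items.get("H", 0)
    ik = items.get("K", 1)
    il = items.get("L", 2)
    ii = items.get("IOBS", 3)
    isig = items.get("SIGMA", 4)
    iz = items.get("ZCAL", 7)
    arr = np.asarray(rows, dtype=float)
    if arr.size and arr.shape[1] <= max(ih, ik, il, ii, isig, iz):
        raise FormatError(f"{path}: too few columns for the INTEGRATE.HKL layout")
    obs = pd.DataFrame(
        {
            "h": arr[:, ih].astype(int),
            "k": arr[:, ik].astype(int),
            "l": arr[:, il].astype(int),
            "intensity": arr[:, ii],
            "sigma": arr[:, isig],
            "image": np.floor(arr[:, iz]).astype(int) + 1,
        }
    ) if arr.size else pd.DataFrame(columns=OBS_COLUMNS)
    return UnmergedDataset(
        dataset_id=path.stem,
        serial=1,
        cell=cell,
        spacegroup="P 1",
        first_image=first,
        last_image=last,
        observations=obs,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# unmerged MTZ dialect (read-only adapter via gemmi)


def _read_mtz_unmerged(path: Path) -> UnmergedDataset:
    import gemmi

    try:
        mtz = gemmi.read_mtz_file(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on garbled files
        raise FormatError(f"{path}: not a readable MTZ file ({exc})") from None
    cols = {c.label: i for i, c in enumerate(mtz.columns)}
    for req in ("H", "K", "L", "I", "SIGI"):
        if req not in cols:
            raise FormatError(f"{path}: MTZ lacks required column {req}")
    batch_label = next((lab for lab in ("BATCH", "M/ISYM") if lab in cols), None)
    arr = np.array(mtz, copy=False)
    if batch_label == "BATCH":
        image = arr[:, cols["BATCH"]].astype(int)
    elif batch_label is not None:
        image = np.ones(len(arr), dtype=int)
    else:
        image = np.ones(len(arr), dtype=int)
    obs = pd.DataFrame(
        {
            "h": arr[:, cols["H"]].astype(int),
            "k": arr[:, cols["K"]].astype(int),
            "l": arr[:, cols["L"]].astype(int),
            "intensity": arr[:, cols["I"]],
            "sigma": arr[:, cols["SIGI"]],
            "image": image,
        }
    )
    c = mtz.cell
    return UnmergedDataset(
        dataset_id=path.stem,
        serial=1,
        cell=UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
        spacegroup=mtz.spacegroup.hm if mtz.spacegroup else "P 1",
        first_image=int(image.min()) if len(image) else 1,
        last_image=int(image.max()) if len(image) else 1,
        observations=obs,
        source_path=str(path),
    )


_DIALECTS = {
    "canonical": _read_canonical,
    "xds_integrate": _read_xds_integrate,
    "mtz_unmerged": _read_mtz_unmerged,
}


def sniff_dialect(path: str | os.PathLike) -> str:
    """Guess the dialect of a reflection file from its leading bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(64)
    if head.startswith(b"MTZ"):
        return "mtz_unmerged"
    if head.lstrip().startswith(b"!"):
        return "xds_integrate"
    return "canonical"


def read_dataset(path: str | os.PathLike, dialect: str = "auto") -> UnmergedDataset:
    """Read one unmerged dataset; ``dialect`` in {auto, canonical, xds_integrate, mtz_unmerged}."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = sniff_dialect(path)
    try:
        reader = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    return reader(path)


# ---------------------------------------------------------------------------
# input gathering and bookkeeping files


def gather_inputs(
    target: str | os.PathLike,
    workdir: str | os.PathLike = ".",
    dialect: str = "auto",
) -> list[UnmergedDataset]:
    """Collect datasets from a directory or a list file; write mtz_names.dat.

    Serials 1..n are assigned in lexicographic order of the (absolute)
    source paths, so repeated runs over the same inputs give identical
    serials.  ``mtz_names.dat`` in ``workdir`` records one absolute path per
    line, in serial order.
    """
    target = Path(target)
    workdir = Path(workdir)
    if target.is_dir():
        paths = sorted(
            p.resolve()
            for p in target.iterdir()
            if p.is_file() and p.suffix.lower() in CANONICAL_EXTENSIONS
            and p.name != "mtz_names.dat"
        )
    elif target.is_file():
        paths = []
        with open(target) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                p = Path(line)
                if not p.is_absolute():
                    p = (target.parent / p).resolve()
                if not p.is_file():
                    raise FileNotFoundError(f"listed input does not exist: {line}")
                paths.append(p)
    else:
        raise FileNotFoundError(target)
    if not paths:
        raise ValueError(f"no input datasets found under {target}")
    datasets = []
    for serial, p in enumerate(paths, 1):
        ds = read_dataset(p, dialect=dialect)
        ds.serial = serial
        datasets.append(ds)
    workdir.mkdir(parents=True, exist_ok=True)
    with open(workdir / "mtz_names.dat", "w") as fh:
        for p in paths:
            fh.write(str(p) + "\n")
    return datasets


def write_final_list(entries: Sequence[FinalListEntry], path: str | os.PathLike) -> None:
    """Write the six-column per-dataset summary, rows ordered by serial.

    A missing cutoff is rendered as the dataset's last image: cutoff equal to
    the last image means no pruning suggested.
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    with open(path, "w") as fh:
        for e in sorted(entries, key=lambda e: e.serial):
            fh.write(
                f"{e.path} {e.serial} {e.effective_cutoff} "
                f"{e.first_image} {e.last_image} {e.suggested_resolution:.3f}\n"
            )


def read_final_list(path: str | os.PathLike) -> list[FinalListEntry]:
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            entries.append(
                FinalListEntry(
                    path=parts[0],
                    serial=int(parts[1]),
                    cutoff_image=int(parts[2]),
                    first_image=int(parts[3]),
                    last_image=int(parts[4]),
                    suggested_resolution=float(parts[5]),
                )
            )
    return entries
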