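"""Symmetry mapping, per-dataset scaling, merging and quality statistics.

This is the internal replacement for the external scaling stage: a minimal
multiplicative scale + isotropic B-factor model per dataset,

    I_scaled = k_j * exp(-2 * B_j * s) * I_obs,      s = 1/d**2,

fitted by alternating least squares against the running merged means, with
the lowest-serial dataset as reference (k = 1, B = 0).  No absorption,
detector or partiality corrections are attempted; the statistics consumed
downstream (R_merge, R_meas, R_pim, completeness, multiplicity, CC1/2,
Mn(I/sd)) only require observations on a common scale.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reflio import KeywordSet, UnitCell, UnmergedDataset

__all__ = [
    "SymmetryOps",
    "MergeStats",
    "MergeResult",
    "ToleranceError",
    "UnconnectedGroupError",
    "map_to_unique",
    "check_tolerance",
    "scale_datasets",
    "merge",
    "compute_stats",
    "merge_group",
    "theoretical_unique_count",
]

log = logging.getLogger(__name__)

_ENC = 2048  # per-component offset base for integer-encoding hkl triples


class ToleranceError(RuntimeError):
    """Cells in a group differ more than the merging tolerance allows."""


class UnconnectedGroupError(RuntimeError):
    """No symmetry-unique reflection is shared between datasets."""


@dataclass(frozen=True)
class SymmetryOps:
    """Rotational symmetry operations acting on Miller indices.

    ``rotations`` are integer 3x3 matrices applied as row-vector products
    h' = h . R; ``friedel`` adds the -h,-k,-l equivalence.
    """

    spacegroup: str
    rotations: tuple
    friedel: bool = True

    def __post_init__(self):
        mats = [np.asarray(r, dtype=int) for r in self.rotations]
        if not any((m == np.eye(3, dtype=int)).all() for m in mats):
            raise ValueError("identity rotation missing")
        keys = {m.tobytes() for m in mats}
        for a in mats:
            for b in mats:
                if (a @ b).astype(int).tobytes() not in keys:
                    raise ValueError("rotation set not closed under composition")
        object.__setattr__(self, "rotations", tuple(tuple(map(tuple, m)) for m in mats))

    @classmethod
    def from_symbol(cls, symbol: str, friedel: bool = True) -> "SymmetryOps":
        """Look up the rotation parts of a Hermann-Mauguin space-group symbol."""
        import gemmi

        sg = gemmi.SpaceGroup(symbol)
        seen = {}
        for op in sg.operations():
            rot = (np.asarray(op.rot, dtype=float) / gemmi.Op.DEN).astype(int)
            seen[rot.tobytes()] = rot
        return cls(spacegroup=symbol, rotations=tuple(seen.values()), friedel=friedel)

    def matrix_stack(self) -> np.ndarray:
        mats = np.array(self.rotations, dtype=np.int64)
        if self.friedel:
            mats = np.concatenate([mats, -mats], axis=0)
        return mats


def map_to_unique(hkl: np.ndarray, ops: SymmetryOps) -> np.ndarray:
    """Canonical (lexicographically greatest) symmetry image of each index.

    ``hkl`` is (n, 3) integer; returns the (n, 3) canonical keys.  All
    members of one orbit map to the same key.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    mats = ops.matrix_stack()                       # (m, 3, 3)
    cand = np.einsum("ni,mij->nmj", hkl, mats)      # (n, m, 3)
    score = (
        (cand[..., 0] + _ENC // 2) * _ENC * _ENC
        + (cand[..., 1] + _ENC // 2) * _ENC
        + (cand[..., 2] + _ENC // 2)
    )
    best = np.argmax(score, axis=1)
    return cand[np.arange(len(hkl)), best]


def check_tolerance(cells: Sequence[UnitCell], tolerance: float = 2.0) -> tuple[bool, str]:
    """Pairwise cell agreement: <= tolerance % on edges, degrees on angles.

    Tolerance >= 100 always passes (merge regardless of cell differences).
    Returns (ok, message); the message names the worst pair on failure.
    """
    if len(cells) < 2:
        return True, "single cell"
    if tolerance >= 100:
        return True, "tolerance >= 100: all cells accepted"
    arr = np.array([c.as_tuple() for c in cells])
    worst = (0.0, "")
    ok = True
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            edge_dev = 100.0 * np.abs(arr[i, :3] - arr[j, :3]) / np.minimum(arr[i, :3], arr[j, :3])
            ang_dev = np.abs(arr[i, 3:] - arr[j, 3:])
            dev = max(edge_dev.max(), ang_dev.max())
            if dev > worst[0]:
                worst = (dev, f"cells {i + 1} and {j + 1} differ by {dev:.2f} (%/deg)")
            if edge_dev.max() > tolerance or ang_dev.max() > tolerance:
                ok = False
    return ok, worst[1] if worst[1] else "all pairs within tolerance"


def _encode(keys: np.ndarray) -> np.ndarray:
    return (
        (keys[:, 0] + _ENC // 2) * _ENC * _ENC
        + (keys[:, 1] + _ENC // 2) * _ENC
        + (keys[:, 2] + _ENC // 2)
    ).astype(np.int64)


def _obs_frame(group: Sequence[UnmergedDataset], ops: SymmetryOps, keywords: KeywordSet) -> pd.DataFrame:
    frames = []
    for ds in group:
        obs = ds.observations
        hkl = ds.hkl()
        s = ds.cell.inv_d2(hkl)
        keep = np.ones(len(obs), dtype=bool)
        if keywords.resolution_high is not None:
            keep &= s <= 1.0 / keywords.resolution_high**2 + 1e-12
        if keywords.resolution_low is not None:
            keep &= s >= 1.0 / keywords.resolution_low**2 - 1e-12
        keys = map_to_unique(hkl[keep], ops)
        frames.append(
            pd.DataFrame(
                {
                    "key_h": keys[:, 0],
                    "key_k": keys[:, 1],
                    "key_l": keys[:, 2],
                    "intensity": obs["intensity"].to_numpy()[keep],
                    "sigma": obs["sigma"].to_numpy()[keep],
                    "serial": ds.serial,
                    "image": obs["image"].to_numpy()[keep],
                    "s": s[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _solve_log_scales(keyinv, n_keys, dsidx, J, s, I):
    """Exact least squares of ln I on per-reflection effects + per-dataset
    (intercept, slope in s), profiling out the reflection effects.

    Only positive intensities on multiply-observed reflections inform the
    fit.  The multiplicative gauge is pinned by dropping the reference's
    intercept column; the B gauge is left to the data and re-expressed
    relative to the reference afterwards.  Returns (k, B) arrays.
    """
    counts_all = np.bincount(keyinv, minlength=n_keys)
    mask = (I > 0) & (counts_all[keyinv] >= 2)
    if mask.sum() < 2:
        return np.ones(J), np.zeros(J)
    ki = keyinv[mask]
    dj = dsidx[mask]
    sx = s[mask]
    y = np.log(I[mask])
    n_h = np.bincount(ki, minlength=n_keys).astype(float)
    # columns: intercepts for datasets 1..J-1, then s-slopes for datasets 0..J-1
    ncol = 2 * J - 1
    flat = ki * J + dj
    S_ind = np.bincount(flat, minlength=n_keys * J).reshape(n_keys, J)[:, 1:]
    S_s = np.bincount(flat, weights=sx, minlength=n_keys * J).reshape(n_keys, J)
    Sy = np.bincount(ki, weights=y, minlength=n_keys)
    A = np.concatenate([S_ind, S_s], axis=1)          # (n_keys, ncol)
    # raw cross products (columns of different datasets never overlap)
    n_j = np.bincount(dj, minlength=J).astype(float)
    s_j = np.bincount(dj, weights=sx, minlength=J)
    ss_j = np.bincount(dj, weights=sx * sx, minlength=J)
    y_j = np.bincount(dj, weights=y, minlength=J)
    sy_j = np.bincount(dj, weights=sx * y, minlength=J)
    G = np.zeros((ncol, ncol))
    G[: J - 1, : J - 1] = np.diag(n_j[1:])
    G[J - 1:, J - 1:] = np.diag(ss_j)
    G[: J - 1, J - 1 + 1:] = np.diag(s_j[1:])
    G[J - 1 + 1:, : J - 1] = np.diag(s_j[1:])
    b = np.concatenate([y_j[1:], sy_j])
    # within-reflection correction
    with np.errstate(divide="ignore", invalid="ignore"):
        An = A / np.where(n_h > 0, n_h, 1.0)[:, None]
    G -= A.T @ An
    b -= An.T @ Sy
    theta, *_ = np.linalg.lstsq(G, b, rcond=None)
    alpha = np.concatenate([[0.0], theta[: J - 1]])
    beta = theta[J - 1:]
    k = np.exp(-alpha)
    B = beta / 2.0
    # express relative to the reference dataset (k_ref = 1, B_ref = 0)
    k /= k[0]
    B = B - B[0]
    return k, B


def scale_datasets(
    group: Sequence[UnmergedDataset],
    ops: SymmetryOps,
    keywords: KeywordSet | None = None,
) -> tuple[dict[int, tuple[float, float]], pd.DataFrame]:
    """Fit per-dataset (k, B) scales against the shared reflection means.

    On the log scale the model ln I = mu_h - ln k_j + 2 B_j s is linear, so
    the per-dataset parameters are obtained by exact least squares with the
    per-reflection effects mu_h profiled out (the simultaneous solution of
    the scale-vs-merged-means regression, rather than an alternating
    approximation to it).  Only positive intensities on multiply-observed
    reflections inform the fit.  The lowest-serial dataset is the reference
    (k = 1, B = 0); sigmas are scaled by the same factor as intensities.

    Returns ({serial: (k, B)}, scaled observation table).
    """
    keywords = keywords or KeywordSet()
    group = sorted(group, key=lambda d: d.serial)
    obs = _obs_frame(group, ops, keywords)
    if len(obs) == 0:
        raise ValueError("no observations left after resolution cuts")
    code = _encode(obs[["key_h", "key_k", "key_l"]].to_numpy())
    uniq, keyinv = np.unique(code, return_inverse=True)
    serials = np.array([ds.serial for ds in group])
    dsidx = np.searchsorted(serials, obs["serial"].to_numpy())
    if len(group) >= 2:
        multi = False
        # a key seen in two distinct datasets connects the group
        seen = {}
        for c, j in zip(code, dsidx):
            prev = seen.get(c)
            if prev is None:
                seen[c] = j
            elif prev != j:
                multi = True
                break
        if not multi:
            raise UnconnectedGroupError(
                "no symmetry-unique reflection observed in >= 2 datasets"
            )
    I = obs["intensity"].to_numpy(dtype=float)
    s = obs["s"].to_numpy(dtype=float)
    J = len(group)
    if J == 1:
        k, B = np.ones(1), np.zeros(1)
    else:
        k, B = _solve_log_scales(keyinv, len(uniq), dsidx, J, s, I)
    factor = k[dsidx] * np.exp(-2.0 * B[dsidx] * s)
    scaled = obs.copy()
    scaled["intensity"] = factor * I
    scaled["sigma"] = factor * obs["sigma"].to_numpy()
    scales = {int(serials[j]): (float(k[j]), float(B[j])) for j in range(J)}
    return scales, scaled


def merge(scaled: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance weighted merge of scaled observations per unique key.

    Returns a table with key_h/k/l, intensity, sigma = (sum 1/sigma^2)^-1/2,
    n_obs and the key's s, sorted by s.
    """
    if len(scaled) == 0:
        raise ValueError("nothing to merge")
    code = _encode(scaled[["key_h", "key_k", "key_l"]].to_numpy())
    uniq, keyinv = np.unique(code, return_inverse=True)
    w = 1.0 / scaled["sigma"].to_numpy() ** 2
    wi = w * scaled["intensity"].to_numpy()
    wsum = np.bincount(keyinv, weights=w)
    merged_i = np.bincount(keyinv, weights=wi) / wsum
    n_obs = np.bincount(keyinv)
    first = np.full(len(uniq), -1, dtype=int)
    first[keyinv[::-1]] = np.arange(len(scaled))[::-1]
    out = pd.DataFrame(
        {
            "key_h": scaled["key_h"].to_numpy()[first],
            "key_k": scaled["key_k"].to_numpy()[first],
            "key_l": scaled["key_l"].to_numpy()[first],
            "intensity": merged_i,
            "sigma": 1.0 / np.sqrt(wsum),
            "n_obs": n_obs,
            "s": scaled["s"].to_numpy()[first],
        }
    )
    return out.sort_values("s", kind="stable").reset_index(drop=True)


def theoretical_unique_count(
    cell: UnitCell, ops: SymmetryOps, d_min: float, return_s: bool = False
):
    """Number of symmetry-unique reflections to d_min by direct enumeration."""
    hmax = int(math.ceil(cell.a / d_min)) + 1
    kmax = int(math.ceil(cell.b / d_min)) + 1
    lmax = int(math.ceil(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[(hkl != 0).any(axis=1)]
    s = cell.inv_d2(hkl)
    keep = s <= 1.0 / d_min**2 + 1e-9
    keys = map_to_unique(hkl[keep], ops)
    code = _encode(keys)
    uniq, idx = np.unique(code, return_index=True)
    if return_s:
        return len(uniq), s[keep][idx]
    return len(uniq)


@dataclass
class MergeStats:
    """Overall and per-shell merging quality statistics.

    R statistics are None when every reflection is observed once.  ``res_cc``
    and ``res_mnisd`` are the finest shell-midpoint resolutions at which the
    shell CC1/2 exceeds 0.3 and the shell Mn(I/sd) exceeds 2.
    """

    r_merge: float | None
    r_meas: float | None
    r_pim: float | None
    completeness: float
    multiplicity: float
    cc_half: float
    mn_i_sd: float
    res_cc: float
    res_mnisd: float
    res_max: float
    per_shell: pd.DataFrame = field(repr=False, default=None)


@dataclass
class MergeResult:
    reflections: pd.DataFrame
    stats: MergeStats
    scales: dict[int, tuple[float, float]]
    members: list[int]
    tag: str = ""
    scaled: pd.DataFrame = field(repr=False, default=None)


def _r_stats(keyinv, counts, I):
    """(r_merge, r_meas, r_pim) over keys with >= 2 observations."""
    multi = counts >= 2
    if not multi.any():
        return None, None, None
    means = np.bincount(keyinv, weights=I) / counts
    dev = np.abs(I - means[keyinv])
    in_multi = multi[keyinv]
    num_key = np.bincount(keyinv, weights=np.where(in_multi, dev, 0.0))
    den = np.bincount(keyinv, weights=np.where(in_multi, I, 0.0)).sum()
    if den <= 0:
        return None, None, None
    n = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_meas = np.sqrt(n / (n - 1.0))
        w_pim = np.sqrt(1.0 / (n - 1.0))
    msel = multi
    r_merge = num_key[msel].sum() / den
    r_meas = (w_meas[msel] * num_key[msel]).sum() / den
    r_pim = (w_pim[msel] * num_key[msel]).sum() / den
    return float(r_merge), float(r_meas), float(r_pim)


def _half_split_cc(keyinv, counts, I, rng):
    """CC1/2 from a random split of each reflection's observations; also
    returns the per-key half means for shell-wise use."""
    n_keys = len(counts)
    u = rng.random(len(I))
    order = np.lexsort((u, keyinv))
    # within each key's contiguous block in `order`, first half -> A
    starts = np.searchsorted(keyinv[order], np.arange(n_keys))
    pos = np.arange(len(I)) - starts[keyinv[order]]
    first_half = pos < counts[keyinv[order]] // 2 + counts[keyinv[order]] % 2
    # keys with n==1 contribute nothing; require both halves non-empty (n>=2)
    a = np.zeros(n_keys)
    b = np.zeros(n_keys)
    na = np.zeros(n_keys)
    nb = np.zeros(n_keys)
    ko = keyinv[order]
    Io = I[order]
    np.add.at(a, ko[first_half], Io[first_half])
    np.add.at(na, ko[first_half], 1)
    np.add.at(b, ko[~first_half], Io[~first_half])
    np.add.at(nb, ko[~first_half], 1)
    ok = (na > 0) & (nb > 0)
    mean_a = np.where(ok, a / np.maximum(na, 1), np.nan)
    mean_b = np.where(ok, b / np.maximum(nb, 1), np.nan)
    return ok, mean_a, mean_b


def _pearson(x, y):
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if len(x) and np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compute_stats(
    scaled: pd.DataFrame,
    merged: pd.DataFrame,
    cell: UnitCell,
    ops: SymmetryOps,
    d_min: float,
    n_shells: int = 10,
    seed: int = 42,
    cc_threshold: float = 0.3,
    mnisd_threshold: float = 2.0,
) -> MergeStats:
    """Standard merging statistics, overall and per resolution shell.

    R statistics use the scaled unmerged intensities around their plain key
    means; completeness compares the observed unique count with a direct
    enumeration of the theoretical unique set to ``d_min``; CC1/2 is the
    Pearson correlation of two merged half-datasets from a seeded random
    split of every reflection's observations.
    """
    if len(merged) == 0:
        raise ValueError("merged table is empty")
    rng = np.random.default_rng(seed)
    code = _encode(scaled[["key_h", "key_k", "key_l"]].to_numpy())
    uniq, keyinv = np.unique(code, return_inverse=True)
    counts = np.bincount(keyinv)
    I = scaled["intensity"].to_numpy(dtype=float)
    r_merge, r_meas, r_pim = _r_stats(keyinv, counts, I)
    n_theor, s_theor = theoretical_unique_count(cell, ops, d_min, return_s=True)
    completeness = 100.0 * len(uniq) / n_theor
    multiplicity = float(len(scaled) / len(uniq))
    ok, mean_a, mean_b = _half_split_cc(keyinv, counts, I, rng)
    cc_half = _pearson(mean_a[ok], mean_b[ok]) if ok.any() else float("nan")
    merged_isig = merged["intensity"].to_numpy() / merged["sigma"].to_numpy()
    mn_i_sd = float(merged_isig.mean())

    # ---- per shell: equal-count bins over observed unique keys in s
    key_s = np.zeros(len(uniq))
    key_s[keyinv] = scaled["s"].to_numpy()
    n_shells = max(1, min(n_shells, max(1, len(uniq) // 10)))
    qs = np.quantile(key_s, np.linspace(0, 1, n_shells + 1))
    qs[0] = 0.0
    qs[-1] = max(qs[-1], 1.0 / d_min**2) + 1e-9
    edges = np.unique(qs)
    key_shell = np.clip(np.searchsorted(edges, key_s, side="right") - 1, 0, len(edges) - 2)
    obs_shell = key_shell[keyinv]
    theor_shell = np.clip(np.searchsorted(edges, s_theor, side="right") - 1, 0, len(edges) - 2)
    m_code = _encode(merged[["key_h", "key_k", "key_l"]].to_numpy())
    m_pos = np.searchsorted(uniq, m_code)
    rows = []
    for j in range(len(edges) - 1):
        kmask = key_shell == j
        omask = obs_shell == j
        if not kmask.any():
            continue
        sub_inv = keyinv[omask]
        remap = -np.ones(len(uniq), dtype=int)
        ks = np.flatnonzero(kmask)
        remap[ks] = np.arange(len(ks))
        rm, rms, rp = _r_stats(remap[sub_inv], counts[kmask], I[omask])
        okj = ok & kmask
        ccj = _pearson(mean_a[okj], mean_b[okj]) if okj.any() else float("nan")
        mmask = kmask[m_pos]
        mnisd_j = float(merged_isig[mmask].mean()) if mmask.any() else float("nan")
        n_theor_j = int((theor_shell == j).sum())
        s_mid = float(0.5 * (edges[j] + edges[j + 1]))
        rows.append(
            {
                "shell": j,
                "s_mid": s_mid,
                "d_mid": 1.0 / math.sqrt(s_mid) if s_mid > 0 else float("inf"),
                "n_unique": int(kmask.sum()),
                "n_obs": int(omask.sum()),
                "completeness": 100.0 * kmask.sum() / max(n_theor_j, 1),
                "multiplicity": float(omask.sum() / kmask.sum()),
                "r_merge": rm,
                "r_meas": rms,
                "r_pim": rp,
                "cc_half": ccj,
                "mn_i_sd": mnisd_j,
            }
        )
    per_shell = pd.DataFrame(rows)

    def finest(col, threshold):
        good = per_shell[per_shell[col] > threshold]
        if len(good):
            return float(1.0 / math.sqrt(good["s_mid"].max()))
        return float(1.0 / math.sqrt(per_shell["s_mid"].min()))

    return MergeStats(
        r_merge=r_merge,
        r_meas=r_meas,
        r_pim=r_pim,
        completeness=float(completeness),
        multiplicity=multiplicity,
        cc_half=cc_half,
        mn_i_sd=mn_i_sd,
        res_cc=finest("cc_half", cc_threshold),
        res_mnisd=finest("mn_i_sd", mnisd_threshold),
        res_max=float(d_min),
        per_shell=per_shell,
    )


def merge_group(
    group: Sequence[UnmergedDataset],
    ops: SymmetryOps | None = None,
    keywords: KeywordSet | None = None,
    tag: str = "",
    n_shells: int = 10,
) -> MergeResult:
    """Tolerance check, scaling, merging and statistics for a dataset group."""
    if not group:
        raise ValueError("empty group")
    keywords = keywords or KeywordSet()
    cells = [ds.cell for ds in group]
    ok, msg = check_tolerance(cells, keywords.tolerance)
    if not ok:
        raise ToleranceError(f"cell tolerance check failed: {msg}")
    if ops is None:
        ops = SymmetryOps.from_symbol(group[0].spacegroup)
    scales, scaled = scale_datasets(group, ops, keywords)
    merged = merge(scaled)
    if keywords.resolution_high is not None:
        d_min = keywords.resolution_high
    else:
        d_min = float(1.0 / math.sqrt(scaled["s"].max()))
    arr = np.array([c.as_tuple() for c in cells])
    mean_cell = UnitCell(*arr.mean(axis=0))
    stats = compute_stats(
        scaled, merged, mean_cell, ops, d_min, n_shells=n_shells, seed=keywords.seed
    )
    return MergeResult(
        reflections=merged,
        stats=stats,
        scales=scales,
        members=sorted(ds.serial for ds in group),
        tag=tag,
        scaled=scaled,
    )
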