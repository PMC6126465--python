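"""Per-dataset resolution estimation from shell-averaged signal/noise.

Unscaled intensities and their errors are averaged in equal-count resolution
shells (all images included, before any damage cutoff).  The ratio
<I>/<sigma> per shell, as a function of s = 1/d**2, is smoothed with a
polynomial of degree min(10, n_shells - 1); the suggested resolution is the
first point of a fine grid at which the polynomial falls below the ISIGI
threshold (default 1.5, a deliberately conservative choice).  If the curve
never crosses, the dataset's own maximum resolution is returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raddam import assess_dataset, equal_count_edges
from .reflio import FinalListEntry, KeywordSet, UnmergedDataset

__all__ = ["ShellSignal", "shell_signal", "estimate_resolution", "analysis_pass"]

log = logging.getLogger(__name__)

GRID_POINTS = 1000


@dataclass
class ShellSignal:
    shell_index: int
    s_mid: float          # 1/A^2
    mean_intensity: float
    mean_sigma: float

    @property
    def ratio(self) -> float:
        return self.mean_intensity / self.mean_sigma


def shell_signal(ds: UnmergedDataset, n_shells: int = 20) -> list[ShellSignal]:
    """Unweighted per-shell means of raw intensities and sigmas (all images)."""
    obs = ds.observations
    if len(obs) == 0:
        raise ValueError(f"dataset {ds.dataset_id}: no observations")
    n_shells = max(1, min(n_shells, max(1, len(obs) // 5)))
    s = ds.inv_d2()
    edges = equal_count_edges(s, n_shells)
    shell = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    intensity = obs["intensity"].to_numpy()
    sigma = obs["sigma"].to_numpy()
    out = []
    for j in range(len(edges) - 1):
        m = shell == j
        if not m.any():
            continue
        out.append(
            ShellSignal(
                shell_index=j,
                s_mid=float(0.5 * (s[m].min() + s[m].max())),
                mean_intensity=float(intensity[m].mean()),
                mean_sigma=float(sigma[m].mean()),
            )
        )
    return out


def estimate_resolution(
    signal: Sequence[ShellSignal], isigi: float = 1.5, d_max_data: float | None = None
) -> float:
    """Resolution (Angstrom) where the smoothed <I>/<sigma> curve crosses isigi.

    The polynomial (degree min(10, n_shells-1), least squares in s) is
    evaluated on a 1000-point grid over the observed s range; the first grid
    point below ``isigi`` wins (lowest-resolution crossing, conservative).
    Returns ``d_max_data`` when the curve never drops below the threshold.
    """
    if len(signal) < 2:
        raise ValueError("resolution estimate needs >= 2 shells")
    s = np.array([sh.s_mid for sh in signal])
    r = np.array([sh.ratio for sh in signal])
    order = np.argsort(s)
    s, r = s[order], r[order]
    if d_max_data is None:
        d_max_data = float(1.0 / math.sqrt(s.max()))
    degree = min(10, len(signal) - 1)
    coeffs = np.polynomial.polynomial.polyfit(s, r, degree)
    grid = np.linspace(s.min(), s.max(), GRID_POINTS)
    values = np.polynomial.polynomial.polyval(grid, coeffs)
    below = values < isigi
    if not below.any():
        return float(d_max_data)
    s_star = grid[int(np.argmax(below))]
    if below[0]:
        log.warning("all data below the I/sigma threshold %.3g", isigi)
    return float(1.0 / math.sqrt(s_star))


def analysis_pass(
    datasets: Sequence[UnmergedDataset],
    keywords: KeywordSet | None = None,
    n_shells: int = 20,
    damage_shells: int = 10,
) -> list[FinalListEntry]:
    """Damage cutoffs + resolution estimates for every dataset.

    Composes the radiation-damage pass (cutoff image, or the last image when
    no damage is flagged) with the resolution estimate into the six-column
    per-dataset summary rows.
    """
    if not datasets:
        raise ValueError("analysis needs at least one dataset")
    keywords = keywords or KeywordSet()
    entries = []
    for ds in datasets:
        assessment = assess_dataset(
            ds, n_shells=damage_shells, radfrac=keywords.radfrac
        )
        resolution = estimate_resolution(
            shell_signal(ds, n_shells=n_shells),
            isigi=keywords.isigi,
            d_max_data=ds.d_min(),
        )
        entries.append(
            FinalListEntry(
                path=ds.source_path or ds.dataset_id,
                serial=ds.serial,
                cutoff_image=assessment.cutoff_image,
                first_image=ds.first_image,
                last_image=ds.last_image,
                suggested_resolution=round(resolution, 3),
            )
        )
    return entries
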