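"""Radiation-damage detection and image-cutoff suggestion.

Dose-dependent intensity decay is fastest at high resolution.  Per resolution
shell the mean positive intensity per image is modelled as a linear
exponential, I = exp(amplitude - decay * image), fitted by ordinary least
squares on the log scale.  A dataset is flagged as damaged when the fitted
decay rate increases significantly with resolution (one-sided weighted
least-squares trend test on decay vs s = 1/d**2).  For a damaged dataset the
cutoff image is the image at which the highest-resolution shell's mean
intensity has dropped to a configurable fraction (RADFRAC) of its value at
the first image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reflio import UnmergedDataset

__all__ = [
    "ShellDecayFit",
    "DamageAssessment",
    "fit_shell_decay",
    "assess_damage",
    "suggest_cutoff",
    "assess_dataset",
]

#: wedges shorter than this are not assessed (too few dose points)
MIN_IMAGES = 5


@dataclass
class ShellDecayFit:
    """Log-linear decay fit for one resolution shell."""

    shell_index: int
    s_mid: float          # 1/A^2 shell midpoint
    amplitude: float      # log-intensity intercept at image 0
    decay: float          # per-image decay rate (>= 0 under damage)
    decay_se: float       # OLS standard error of the decay estimate
    n_obs: int


@dataclass
class DamageAssessment:
    serial: int
    fits: list[ShellDecayFit]
    damaged: bool
    trend_slope: float
    trend_pvalue: float
    cutoff_image: int | None = None


def equal_count_edges(s: np.ndarray, n_shells: int) -> np.ndarray:
    """Shell edges in s with (near) equal observation counts per shell."""
    qs = np.linspace(0, 1, n_shells + 1)
    edges = np.quantile(s, qs)
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return np.unique(edges)


def fit_shell_decay(ds: UnmergedDataset, n_shells: int = 10) -> list[ShellDecayFit]:
    """Per-shell OLS of ln(positive intensity) on image number.

    Shells are equal-count bins in s = 1/d**2.  The regression runs over the
    individual positive observations (for a balanced design the slope equals
    the regression on per-image log means, but the residuals are independent
    so the slope's standard error is honestly calibrated, which the damage
    trend test relies on).  Non-positive observations are skipped; shells
    observed on fewer than 3 distinct usable images are omitted.  Returns []
    when nothing is fittable.
    """
    obs = ds.observations
    if len(obs) == 0 or obs["image"].nunique() < 2:
        return []
    s = ds.inv_d2()
    n_shells = max(1, min(n_shells, len(obs) // 3))
    edges = equal_count_edges(s, n_shells)
    shell = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, len(edges) - 2)
    intensity = obs["intensity"].to_numpy()
    image = obs["image"].to_numpy().astype(float)
    fits: list[ShellDecayFit] = []
    for j in range(len(edges) - 1):
        in_shell = shell == j
        pos = in_shell & (intensity > 0)
        if pos.sum() < 3 or len(np.unique(image[pos])) < 3:
            continue
        result = stats.linregress(image[pos], np.log(intensity[pos]))
        s_in = s[in_shell]
        fits.append(
            ShellDecayFit(
                shell_index=j,
                s_mid=float(0.5 * (s_in.min() + s_in.max())),
                amplitude=float(result.intercept),
                decay=float(-result.slope),
                decay_se=float(result.stderr),
                n_obs=int(pos.sum()),
            )
        )
    return fits


def assess_damage(
    fits: list[ShellDecayFit], alpha: float = 0.05, serial: int = 0
) -> DamageAssessment:
    """Trend test: is the decay rate increasing with resolution?

    Weighted least squares of decay on s_mid with weights 1/se**2 (plain OLS
    when the per-shell standard errors are degenerate); damaged iff the slope
    is positive with one-sided p < alpha.  Requires >= 3 fitted shells.
    """
    if len(fits) < 3:
        return DamageAssessment(serial, fits, False, 0.0, 1.0)
    s = np.array([f.s_mid for f in fits])
    b = np.array([f.decay for f in fits])
    se = np.array([f.decay_se for f in fits])
    if np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(se)
    W = w.sum()
    sbar = (w * s).sum() / W
    bbar = (w * b).sum() / W
    sxx = (w * (s - sbar) ** 2).sum()
    if sxx <= 0:
        return DamageAssessment(serial, fits, False, 0.0, 1.0)
    slope = (w * (s - sbar) * (b - bbar)).sum() / sxx
    resid = b - bbar - slope * (s - sbar)
    df = len(fits) - 2
    sigma2 = (w * resid**2).sum() / df
    slope_se = math.sqrt(sigma2 / sxx)
    if slope_se == 0:
        pvalue = 0.0 if slope > 0 else 1.0
    else:
        t = slope / slope_se
        pvalue = float(stats.t.sf(t, df))
    return DamageAssessment(
        serial, fits, bool(slope > 0 and pvalue < alpha), float(slope), pvalue
    )


def suggest_cutoff(
    assessment: DamageAssessment, ds: UnmergedDataset, radfrac: float = 0.75
) -> int | None:
    """Last accepted image: where the top shell's intensity drops to radfrac.

    Using the highest-resolution fitted shell's decay B, the mean intensity
    falls to radfrac of its first-image value after ln(1/radfrac)/B images;
    the cutoff is first_image - 1 + floor(ln(1/radfrac)/B), clamped to the
    dataset's image range.  None when not damaged or B <= 0.
    """
    if not assessment.damaged or not assessment.fits:
        return None
    top = max(assessment.fits, key=lambda f: f.s_mid)
    if top.decay <= 0:
        return None
    cutoff = ds.first_image - 1 + math.floor(math.log(1.0 / radfrac) / top.decay)
    return int(min(max(cutoff, ds.first_image), ds.last_image))


def assess_dataset(
    ds: UnmergedDataset,
    n_shells: int = 10,
    alpha: float = 0.05,
    radfrac: float = 0.75,
) -> DamageAssessment:
    """Full per-dataset damage pass: shell fits, trend test, cutoff."""
    if ds.n_images < MIN_IMAGES:
        return DamageAssessment(ds.serial, [], False, 0.0, 1.0)
    fits = fit_shell_decay(ds, n_shells=n_shells)
    assessment = assess_damage(fits, alpha=alpha, serial=ds.serial)
    assessment.cutoff_image = suggest_cutoff(assessment, ds, radfrac=radfrac)
    return assessment
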