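"""Voxelwise and scalar quality measures for EPI time series.

Implements the derived maps and summary numbers used to judge signal
quality after preprocessing:

* **TSNR** — per voxel, mean(signal series) / sd(noise series), where the
  "signal" and "noise" series differ by processing stage: right after
  volume registration the noise is the polynomially detrended series;
  after regression the noise is the residual (errts) series.
* **GCOR** — global correlation: the average over *all* voxel pairs
  (self pairs included) of the Pearson correlation of their time series,
  computed cheaply as the squared norm of the mean unit-normalized series.
* **corr_brain** — each voxel's residual series correlated with the
  brain-average residual ("global residual").
* **radcor** — radial correlation: each voxel against a Gaussian-weighted
  (FWHM 20 mm by default) average of its large neighborhood; sensitive to
  coil artifacts and motion residue that correlate wide patches.
* **seed correlation** maps for user-supplied seed locations.
* **grayplot / carpet plot** — the V x T matrix of Z-scored voxel series,
  rows ordered by similarity to the first principal component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage, stats

from .data_io import VolumeSeries

__all__ = [
    "StatVolume",
    "GrayplotMatrix",
    "detrend_poly",
    "tsnr_map",
    "tsnr_volreg",
    "tsnr_regress",
    "gcor",
    "corr_brain",
    "radial_correlate",
    "seed_corr",
    "grayplot",
]


@dataclass
class StatVolume:
    """A 3D derived statistic map with its provenance tag."""

    data: np.ndarray
    kind: str  # tsnr | corr | radcor
    stage: str = ""
    mask: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)


@dataclass
class GrayplotMatrix:
    """V x T matrix of clipped Z-scores, rows ordered for display."""

    values: np.ndarray
    row_order: np.ndarray
    clip: float
    motion: Optional[np.ndarray] = None
    outliers: Optional[np.ndarray] = None


def _run_slices(n_t: int, run_lengths) -> list[slice]:
    if run_lengths is None:
        return [slice(0, n_t)]
    if sum(run_lengths) != n_t:
        raise ValueError(f"run lengths {list(run_lengths)} do not sum to {n_t}")
    out, start = [], 0
    for n in run_lengths:
        out.append(slice(start, start + n))
        start += n
    return out


def _mask_rows(vol: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape3d:
        raise ValueError(f"mask shape {mask.shape} != volume grid {vol.shape3d}")
    if not mask.any():
        raise ValueError("mask is empty")
    return vol.data[mask]


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend_poly(series: np.ndarray, order: int, run_lengths=None) -> np.ndarray:
    """Remove a per-run Legendre polynomial fit from each row of V x T data.

    The fit is an ordinary least-squares projection onto Legendre
    polynomials of degree 0..order over each run, the standard slow-drift
    baseline model.  Returns the residual matrix (same shape).
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    out = np.empty_like(arr)
    for sl in _run_slices(arr.shape[1], run_lengths):
        n = sl.stop - sl.start
        if n < order + 2:
            raise ValueError(
                f"run of length {n} too short for polynomial order {order}"
            )
        x = np.linspace(-1.0, 1.0, n)
        basis = legendre.legvander(x, order)  # n x (order+1)
        coef, *_ = np.linalg.lstsq(basis, arr[:, sl].T, rcond=None)
        out[:, sl] = arr[:, sl] - (basis @ coef).T
    return out


# ---------------------------------------------------------------------------
# TSNR
# ---------------------------------------------------------------------------

def tsnr_map(
    signal: VolumeSeries,
    noise: VolumeSeries,
    mask: np.ndarray,
    stage: str = "",
) -> StatVolume:
    """Per-voxel TSNR = mean(signal series) / sd(noise series).

    Voxels with zero noise variance get TSNR 0 and are counted in
    ``extras['n_zero_sd']``.  ``extras['tsnr_average']`` holds the masked
    mean, the "TSNR average" review quantity.
    """
    if signal.shape3d != noise.shape3d or signal.n_t != noise.n_t:
        raise ValueError("signal and noise series must share grid and length")
    if signal.n_t < 2:
        raise ValueError("need at least 2 time points for TSNR")
    mask = np.asarray(mask).astype(bool)
    sig = signal.data[mask]
    noi = noise.data[mask]
    mean = sig.mean(axis=1)
    sd = noi.std(axis=1, ddof=1)
    tsnr = np.zeros(sig.shape[0])
    ok = sd > 0
    tsnr[ok] = mean[ok] / sd[ok]
    vol = np.zeros(signal.shape3d)
    vol[mask] = tsnr
    return StatVolume(
        data=vol,
        kind="tsnr",
        stage=stage,
        mask=mask,
        extras={
            "n_zero_sd": int(np.count_nonzero(~ok)),
            "tsnr_average": float(tsnr.mean()) if tsnr.size else 0.0,
        },
    )


def tsnr_volreg(
    vol: VolumeSeries, mask: np.ndarray, detrend_order: int = 2
) -> StatVolume:
    """TSNR stage preset: signal = full series, noise = detrended series."""
    mask_b = np.asarray(mask).astype(bool)
    resid = np.zeros_like(vol.data)
    resid[mask_b] = detrend_poly(vol.data[mask_b], detrend_order, vol.run_lengths)
    noise = VolumeSeries(
        resid, vol.voxdims, vol.tr, vol.orient, list(vol.run_lengths), vol.affine
    )
    return tsnr_map(vol, noise, mask_b, stage="volreg")


def tsnr_regress(
    vol: VolumeSeries, errts: VolumeSeries, mask: np.ndarray
) -> StatVolume:
    """TSNR stage preset: signal = full series, noise = regression residuals."""
    return tsnr_map(vol, errts, mask, stage="regress")


# ---------------------------------------------------------------------------
# correlation measures
# ---------------------------------------------------------------------------

def gcor(vol: VolumeSeries, mask: np.ndarray) -> float:
    """Global correlation: mean of the full voxel-pair correlation matrix.

    Self-correlations are included, so the value equals the squared norm
    of the mean of the unit-normalized (demeaned, L2-scaled) time series
    and lies in [0, 1].  Zero-variance voxels are excluded.
    """
    rows = _mask_rows(vol, mask)
    rows = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    if np.count_nonzero(ok) < 2:
        raise ValueError("need at least 2 voxels with temporal variance")
    unit = rows[ok] / norms[ok, None]
    gmean = unit.mean(axis=0)
    return float(gmean @ gmean)


def corr_brain(
    errts: VolumeSeries,
    mask: np.ndarray,
    display_thr: float = 0.3,
    display_range: float = 0.6,
) -> StatVolume:
    """Correlate each voxel's residual series with the brain-mean residual.

    Display conventions carried in ``extras``: transparent threshold at
    |r| = 0.3 and colorbar bounds at |r| = 0.6.
    """
    rows = _mask_rows(errts, mask)
    gmean = rows.mean(axis=0)
    g = gmean - gmean.mean()
    gnorm = np.linalg.norm(g)
    if gnorm == 0:
        raise ValueError("global mean residual has zero variance")
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    r = np.zeros(rows.shape[0])
    ok = norms > 0
    r[ok] = (centered[ok] @ g) / (norms[ok] * gnorm)
    vol = np.zeros(errts.shape3d)
    vol[np.asarray(mask, dtype=bool)] = r
    return StatVolume(
        data=vol,
        kind="corr",
        stage="corr_brain",
        mask=np.asarray(mask, dtype=bool),
        extras={"display_thr": display_thr, "display_range": display_range},
    )


FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def radial_correlate(
    vol: VolumeSeries,
    mask: np.ndarray,
    fwhm_mm: float = 20.0,
    truncate: float = 3.0,
) -> StatVolume:
    """Radial correlation: each voxel vs its Gaussian-weighted neighborhood.

    The neighborhood average at each voxel is a Gaussian-weighted (sigma =
    fwhm / 2.3548 per axis, in mm; kernel truncated at ``truncate`` sigma)
    mean over in-mask voxels, self included, computed separably as
    smooth(data * mask) / smooth(mask).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    mask_b = np.asarray(mask).astype(bool)
    if mask_b.shape != vol.shape3d:
        raise ValueError("mask grid mismatch")
    if not mask_b.any():
        raise ValueError("mask is empty")
    sigma_vox = tuple((fwhm_mm / FWHM_TO_SIGMA) / v for v in vol.voxdims)
    masked = vol.data * mask_b[..., None]
    sm_data = ndimage.gaussian_filter(
        masked, sigma=sigma_vox + (0.0,), truncate=truncate, mode="constant"
    )
    sm_mask = ndimage.gaussian_filter(
        mask_b.astype(float), sigma=sigma_vox, truncate=truncate, mode="constant"
    )
    navg = sm_data[mask_b] / sm_mask[mask_b][:, None]
    rows = vol.data[mask_b]
    r = _rowwise_pearson(rows, navg)
    out = np.zeros(vol.shape3d)
    out[mask_b] = r
    return StatVolume(out, kind="radcor", mask=mask_b, extras={"fwhm_mm": fwhm_mm})


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two V x T matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    r = np.zeros(a.shape[0])
    ok = (na > 0) & (nb > 0)
    r[ok] = np.einsum("ij,ij->i", ac[ok], bc[ok]) / (na[ok] * nb[ok])
    # single-voxel neighborhoods correlate perfectly with themselves
    self_ok = (na == 0) & (nb == 0) & np.all(np.isclose(a, b), axis=1)
    r[self_ok & ~ok] = 1.0
    return np.clip(r, -1.0, 1.0)


def seed_corr(
    vol: VolumeSeries,
    mask: np.ndarray,
    seed_ijk: tuple[int, int, int],
    seed_radius_mm: float = 0.0,
) -> StatVolume:
    """Seed-based correlation map.

    The seed series is the mean over in-mask voxels within
    ``seed_radius_mm`` (Euclidean, in mm) of ``seed_ijk``; radius 0 uses
    the seed voxel alone.
    """
    mask_b = np.asarray(mask).astype(bool)
    ijk = tuple(int(i) for i in seed_ijk)
    if any(i < 0 or i >= s for i, s in zip(ijk, vol.shape3d)):
        raise ValueError(f"seed {ijk} outside grid {vol.shape3d}")
    if not mask_b[ijk]:
        raise ValueError(f"seed {ijk} is outside the mask")
    idx = np.argwhere(mask_b)
    offsets = (idx - np.array(ijk)) * np.array(vol.voxdims)
    within = np.linalg.norm(offsets, axis=1) <= seed_radius_mm + 1e-9
    sel = idx[within]
    seed_series = vol.data[sel[:, 0], sel[:, 1], sel[:, 2]].mean(axis=0)
    rows = vol.data[mask_b]
    r = _rowwise_pearson(rows, np.broadcast_to(seed_series, rows.shape))
    out = np.zeros(vol.shape3d)
    out[mask_b] = r
    return StatVolume(
        out, kind="corr", stage="seed",
        mask=mask_b, extras={"seed_ijk": ijk, "radius_mm": seed_radius_mm},
    )


# ---------------------------------------------------------------------------
# grayplot
# ---------------------------------------------------------------------------

def grayplot(
    vol: VolumeSeries,
    mask: np.ndarray,
    order_mode: str = "similarity",
    clip_p: float = 0.001,
    detrend_order: int = 2,
    motion: np.ndarray | None = None,
    outliers: np.ndarray | None = None,
) -> GrayplotMatrix:
    """Build the carpet-plot matrix of Z-scored voxel time series.

    Each in-mask series is detrended (per run, Legendre order
    ``detrend_order``) and Z-scored, then clipped at the two-sided normal
    tail value for ``clip_p`` (about 3.2905 for p = 0.001) so grayscale
    ranges are comparable across subjects.  In ``similarity`` mode, rows
    are sorted by decreasing |r| with the first principal component of the
    standardized data (sign fixed so PC1 correlates nonnegatively with the
    mean series; ties broken by voxel index).
    """
    if order_mode not in ("similarity", "unsorted"):
        raise ValueError(f"unknown order_mode {order_mode!r}")
    rows = _mask_rows(vol, mask)
    resid = detrend_poly(rows, detrend_order, vol.run_lengths)
    sd = resid.std(axis=1)
    z = np.zeros_like(resid)
    ok = sd > 0
    z[ok] = resid[ok] / sd[ok, None]

    clip = float(stats.norm.isf(clip_p / 2.0))

    if order_mode == "similarity" and np.count_nonzero(ok) >= 1:
        # PC1 of the standardized data via SVD of the usable rows
        _, _, vt = np.linalg.svd(z[ok], full_matrices=False)
        pc1 = vt[0]
        mean_series = z[ok].mean(axis=0)
        if pc1 @ mean_series < 0:
            pc1 = -pc1
        r = _rowwise_pearson(z, np.broadcast_to(pc1, z.shape))
        order = np.argsort(-np.abs(r), kind="stable")
    else:
        order = np.arange(z.shape[0])

    values = np.clip(z[order], -clip, clip)
    return GrayplotMatrix(
        values=values,
        row_order=order,
        clip=clip,
        motion=None if motion is None else np.asarray(motion, dtype=float),
        outliers=None if outliers is None else np.asarray(outliers, dtype=float),
    )
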