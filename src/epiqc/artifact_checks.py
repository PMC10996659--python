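"""Artifact detectors: left-right flips, variance lines, intensity flags.

Three detectors target problems seen repeatedly in shared EPI data:

* **Left-right flip check.**  A local Pearson correlation (LPC) cost —
  the negative weighted mean of signed block-wise correlations — is
  compared between the anatomical as given and its left-right mirror.
  A clearly lower (better) cost for the mirrored volume means the EPI
  and anatomical disagree about left and right.  Inputs must already
  share a grid; no registration is performed here.
* **Variance lines.**  Scanner artifacts can print narrow through-plane
  columns of excess temporal variance.  Per in-plane (i, j) location the
  90th percentile of voxelwise detrended/scaled temporal sd along the
  slice axis is compared against its in-plane neighborhood median.
* **Raw intensity range.**  Negative stored values hint at conversion
  problems; a stored maximum of exactly 4095 flags possible 12-bit
  saturation.

Warning levels are graded none < undecided < mild < medium < severe, and
a block's displayed level is the maximum over its checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import VolumeSeries
from .quality_maps import detrend_poly

__all__ = [
    "WarnLevel",
    "WARN_ORDER",
    "lpc_cost",
    "flip_check",
    "variance_lines",
    "data_range_check",
    "aggregate_warns",
    "DEFAULT_WARN_LEVELS",
]

WARN_ORDER = ("none", "undecided", "mild", "medium", "severe")

# which warning level each detector outcome maps to in a report
DEFAULT_WARN_LEVELS = {
    "flip_DO_FLIP": "severe",
    "flip_ambiguous": "undecided",
    "flip_NO_FLIP": "none",
    "variance_lines_any": "medium",
    "pre_steady_any": "medium",
    "saturation": "mild",
    "negative_min": "mild",
    "df_left_negative": "severe",
}


@total_ordering
@dataclass(frozen=True)
class WarnLevel:
    """A graded warning: none < undecided < mild < medium < severe."""

    level: str
    message: str = ""

    def __post_init__(self) -> None:
        if self.level not in WARN_ORDER:
            raise ValueError(f"unknown warning level {self.level!r}")

    @property
    def rank(self) -> int:
        return WARN_ORDER.index(self.level)

    def __lt__(self, other: "WarnLevel") -> bool:
        return self.rank < other.rank

    def __eq__(self, other) -> bool:
        return isinstance(other, WarnLevel) and self.rank == other.rank


def aggregate_warns(warns: Sequence[WarnLevel]) -> WarnLevel:
    """Maximum warning level of a collection; empty input is 'none'."""
    if not warns:
        return WarnLevel("none")
    return max(warns)


# ---------------------------------------------------------------------------
# local Pearson correlation cost and the flip check
# ---------------------------------------------------------------------------

def lpc_cost(
    u: np.ndarray,
    v: np.ndarray,
    mask: np.ndarray,
    block_vox: int = 5,
    min_block_vox: int = 8,
) -> float:
    """Local Pearson correlation cost between two 3D volumes.

    The mask is partitioned into non-overlapping ``block_vox``-cubed
    blocks; within each block with at least ``min_block_vox`` in-mask
    voxels (and nonconstant values in both inputs) the signed Pearson r
    is computed, and the cost is minus the in-mask-count-weighted mean of
    those correlations.  Lower is better; range [-1, 1].
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    mask_b = np.asarray(mask).astype(bool)
    if u.shape != v.shape or u.shape != mask_b.shape:
        raise ValueError("volumes and mask must share a grid")
    total_w = 0.0
    total = 0.0
    nx, ny, nz = u.shape
    for x0 in range(0, nx, block_vox):
        for y0 in range(0, ny, block_vox):
            for z0 in range(0, nz, block_vox):
                blk = (
                    slice(x0, x0 + block_vox),
                    slice(y0, y0 + block_vox),
                    slice(z0, z0 + block_vox),
                )
                m = mask_b[blk]
                w = int(m.sum())
                if w < min_block_vox:
                    continue
                a = u[blk][m]
                b = v[blk][m]
                a = a - a.mean()
                b = b - b.mean()
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na == 0 or nb == 0:
                    continue
                r = float(a @ b / (na * nb))
                total += w * r
                total_w += w
    if total_w == 0:
        raise ValueError("no valid blocks (mask too sparse or data constant)")
    return -total / total_w


def _lr_axis(orient: str) -> int:
    """Array axis running left-right, from a 3-letter orientation code."""
    for axis, code in enumerate(orient.upper()):
        if code in ("L", "R"):
            return axis
    raise ValueError(f"orientation code {orient!r} has no left-right axis")


def flip_check(
    epi_ref: np.ndarray,
    anat: np.ndarray,
    mask: np.ndarray,
    orient: str = "RAS",
    block_vox: int = 5,
    tie_tol: float = 1e-6,
) -> dict:
    """Compare alignment cost as-is vs with a left-right flipped anatomical.

    Both volumes must be pre-aligned on one grid.  The anatomical is
    mirrored across the left-right axis named by ``orient`` and the LPC
    cost recomputed; the guess is DO_FLIP when the flipped cost is lower
    by more than ``tie_tol``, NO_FLIP in the reverse case, else
    ambiguous.
    """
    axis = _lr_axis(orient)
    cost_asis = lpc_cost(epi_ref, anat, mask, block_vox=block_vox)
    cost_flipped = lpc_cost(epi_ref, np.flip(anat, axis=axis), mask, block_vox=block_vox)
    if cost_flipped < cost_asis - tie_tol:
        guess = "DO_FLIP"
    elif cost_asis < cost_flipped - tie_tol:
        guess = "NO_FLIP"
    else:
        guess = "ambiguous"
    return {"cost_asis": cost_asis, "cost_flipped": cost_flipped, "guess": guess}


# ---------------------------------------------------------------------------
# variance lines
# ---------------------------------------------------------------------------

def variance_lines(
    vol: VolumeSeries,
    mask: np.ndarray,
    ratio_thresh: float = 3.0,
    detrend_order: int = 2,
    neighborhood: int = 11,
    percentile: float = 90.0,
    keep: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Detect through-plane columns of artifactually high temporal variance.

    Per in-mask voxel the temporal sd of the detrended, mean-scaled series
    is computed.  Per in-plane (i, j), the column score is the
    ``percentile``-th percentile of sd along the slice axis (third voxel
    axis).  Candidates are columns whose score is at least
    ``ratio_thresh`` times the median score in an 11 x 11 in-plane
    neighborhood; adjacent candidates are merged, reporting each
    component's peak.  Returns a table with columns
    ``i, j, k, score, x, y, z`` (score = variance ratio).

    ``keep`` (length-T binary, 1 = keep) restricts the variance estimate
    to uncensored time points, so motion-censored volumes cannot fake
    high-variance columns.
    """
    mask_b = np.asarray(mask).astype(bool)
    if mask_b.shape != vol.shape3d:
        raise ValueError("mask grid mismatch")
    n_slices = np.unique(np.argwhere(mask_b)[:, 2]).size if mask_b.any() else 0
    if n_slices < 2:
        raise ValueError("mask must cover at least 2 slices along the slice axis")

    rows = vol.data[mask_b]
    run_lengths = list(vol.run_lengths)
    if keep is not None:
        keep_b = np.asarray(keep).astype(bool)
        if keep_b.size != rows.shape[1]:
            raise ValueError("keep vector length does not match series")
        kept_lengths, start = [], 0
        for n in run_lengths:
            kept_lengths.append(int(keep_b[start:start + n].sum()))
            start += n
        if any(n < detrend_order + 2 for n in kept_lengths):
            raise ValueError("too few kept time points per run")
        rows = rows[:, keep_b]
        run_lengths = kept_lengths
    means = rows.mean(axis=1, keepdims=True)
    scale = np.where(np.abs(means) > 0, means, 1.0)
    resid = detrend_poly(rows / scale, detrend_order, run_lengths)
    sd_map = np.zeros(vol.shape3d)
    sd_map[mask_b] = resid.std(axis=1)

    nx, ny, _ = vol.shape3d
    col_valid = mask_b.any(axis=2)
    scores = np.full((nx, ny), np.nan)
    peaks = np.zeros((nx, ny), dtype=int)
    for i, j in np.argwhere(col_valid):
        in_col = mask_b[i, j, :]
        vals = sd_map[i, j, in_col]
        scores[i, j] = np.percentile(vals, percentile)
        peaks[i, j] = int(np.flatnonzero(in_col)[np.argmax(vals)])

    half = neighborhood // 2
    ratio = np.zeros((nx, ny))
    for i, j in np.argwhere(col_valid):
        nb = scores[
            max(0, i - half): i + half + 1, max(0, j - half): j + half + 1
        ]
        med = np.nanmedian(nb)
        if med > 0:
            ratio[i, j] = scores[i, j] / med

    candidates = ratio >= ratio_thresh
    labeled, n_comp = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    records = []
    for comp in range(1, n_comp + 1):
        sel = labeled == comp
        masked_ratio = np.where(sel, ratio, -np.inf)
        i, j = np.unravel_index(np.argmax(masked_ratio), masked_ratio.shape)
        k = peaks[i, j]
        xyz = vol.affine @ np.array([i, j, k, 1.0])
        records.append(
            {"i": int(i), "j": int(j), "k": int(k),
             "score": float(ratio[i, j]),
             "x": float(xyz[0]), "y": float(xyz[1]), "z": float(xyz[2])}
        )
    records.sort(key=lambda r: -r["score"])
    return pd.DataFrame(records, columns=["i", "j", "k", "score", "x", "y", "z"])


# ---------------------------------------------------------------------------
# intensity range
# ---------------------------------------------------------------------------

def data_range_check(vol: VolumeSeries) -> dict:
    """Min/max of the stored (unscaled) data, with problem flags.

    Flags ``negative_min`` when the stored minimum is below zero and
    ``saturation`` when the stored maximum is exactly 4095 (a possibly
    saturated 12-bit signal).
    """
    flags = []
    if vol.stored_min < 0:
        flags.append("negative_min")
    if vol.stored_max == 4095:
        flags.append("saturation")
    return {"min": vol.stored_min, "max": vol.stored_max, "flags": flags}
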