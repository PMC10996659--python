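"""Per-ROI TSNR and shape statistics, with graded warnings.

For each region of an integer-labeled atlas the table reports voxel
counts (Nvox), zero-statistic counts (Nzer), the maximum erosion depth in
voxels (Dvox — how "thick" the region is; thin or fragmented regions are
unstable to estimate in), the TSNR five-number summary over nonzero
voxels, and the coordinate of a maximum-depth voxel as the region's
central location.  Warnings grade each cell: many zero voxels, shallow
depth, low T75 or a steep interquartile slope all hint that the region's
signal cannot support reliable estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .quality_maps import StatVolume

__all__ = [
    "ROITableRow",
    "roi_depth",
    "roi_table",
    "roi_warn",
    "mask_dice",
    "DEFAULT_ROI_WARN",
]

# graded thresholds per table cell; directions per the cell's semantics
DEFAULT_ROI_WARN = {
    # Nvox small (<=): instability from tiny regions
    "nvox": {"mild": 20, "medium": 10, "severe": 5},
    # Nzer/Nvox large (>=): region falls outside data support
    "nzer_frac": {"mild": 0.05, "medium": 0.25, "severe": 0.75},
    # Dvox small (<=): thin region, partial-volume dominated
    "dvox": {"mild": 3, "medium": 2, "severe": 1},
    # T75 low (<): weak signal even in the better half of the region
    "t75": {"mild": 80.0, "medium": 50.0, "severe": 20.0},
    # (T75-T25)/Tmed large (>=): steep TSNR drop-off across the region
    "slope": {"mild": 0.4, "medium": 0.75, "severe": 1.0},
}


@dataclass
class ROITableRow:
    """One atlas region's shape and TSNR summary."""

    label: str
    nvox: int
    nzer: int
    dvox: int
    tmin: float
    t25: float
    tmed: float
    t75: float
    tmax: float
    peak_ijk: tuple[int, int, int]
    peak_xyz: tuple[float, float, float]
    warns: dict = field(default_factory=dict)
    all_zero: bool = False


def roi_depth(roi_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Erosion depth of every voxel of a binary mask, plus the maximum.

    A voxel's depth is the iteration at which repeated 6-neighbor
    (face-adjacent) erosion removes it, with out-of-grid counted as
    background: surface voxels have depth 1.  Returns (depth map, Dvox).
    """
    cur = np.asarray(roi_mask).astype(bool)
    if cur.ndim != 3:
        raise ValueError("ROI mask must be 3D")
    if not cur.any():
        raise ValueError("ROI mask is empty")
    structure = ndimage.generate_binary_structure(3, 1)
    depth = np.zeros(cur.shape, dtype=int)
    it = 0
    while cur.any():
        it += 1
        eroded = ndimage.binary_erosion(cur, structure=structure, border_value=0)
        depth[cur & ~eroded] = it
        cur = eroded
    return depth, it


def roi_table(
    tsnr: StatVolume | np.ndarray,
    atlas: np.ndarray,
    labels: Optional[dict[int, str]] = None,
    affine: Optional[np.ndarray] = None,
    warn_config: dict = DEFAULT_ROI_WARN,
) -> list[ROITableRow]:
    """Shape and TSNR summary rows, one per distinct nonzero atlas label.

    Quartiles (linear interpolation) are over nonzero-TSNR voxels only;
    a region entirely without TSNR support reports zeros with a severe
    warning.  The region's coordinate is a maximum-depth voxel, ties
    broken by smallest (i, j, k) lexicographically.
    """
    data = tsnr.data if isinstance(tsnr, StatVolume) else np.asarray(tsnr, float)
    atlas = np.asarray(atlas)
    if atlas.shape != data.shape:
        raise ValueError("atlas grid does not match the statistic volume")
    values = np.unique(atlas)
    values = values[values != 0]
    if values.size == 0:
        raise ValueError("atlas has no nonzero labels")
    if affine is None:
        affine = np.eye(4)

    rows = []
    for val in values:
        sel = atlas == val
        nvox = int(sel.sum())
        vals = data[sel]
        nonzero = vals[vals != 0]
        nzer = nvox - nonzero.size
        depth, dvox = roi_depth(sel)
        peak_candidates = np.argwhere(depth == dvox)
        # np.argwhere returns C order == ascending lexicographic (i, j, k)
        peak = tuple(int(c) for c in peak_candidates[0])
        xyz = affine @ np.array([*peak, 1.0])
        if nonzero.size:
            q = np.percentile(nonzero, [0, 25, 50, 75, 100])
            all_zero = False
        else:
            q = np.zeros(5)
            all_zero = True
        row = ROITableRow(
            label=labels.get(int(val), str(int(val))) if labels else str(int(val)),
            nvox=nvox, nzer=nzer, dvox=dvox,
            tmin=float(q[0]), t25=float(q[1]), tmed=float(q[2]),
            t75=float(q[3]), tmax=float(q[4]),
            peak_ijk=peak, peak_xyz=tuple(float(c) for c in xyz[:3]),
            all_zero=all_zero,
        )
        row.warns = roi_warn(row, warn_config)
        rows.append(row)
    return rows


def _grade(value: float, thresholds: dict, low_is_bad: bool) -> str:
    for level in ("severe", "medium", "mild"):
        t = thresholds[level]
        if (low_is_bad and value <= t) or (not low_is_bad and value >= t):
            return level
    return "none"


def roi_warn(row: ROITableRow, config: dict = DEFAULT_ROI_WARN) -> dict:
    """Graded warning level per table cell of one ROI row."""
    warns = {
        "nvox": _grade(row.nvox, config["nvox"], low_is_bad=True),
        "nzer_frac": _grade(
            row.nzer / row.nvox if row.nvox else 1.0,
            config["nzer_frac"], low_is_bad=False,
        ),
        "dvox": _grade(row.dvox, config["dvox"], low_is_bad=True),
    }
    if row.all_zero:
        warns["t75"] = "severe"
        warns["slope"] = "severe"
    else:
        # low T75 graded strictly-below, unlike the <= small-count cells
        t75 = "none"
        for level in ("severe", "medium", "mild"):
            if row.t75 < config["t75"][level]:
                t75 = level
                break
        warns["t75"] = t75
        if row.tmed == 0:
            warns["slope"] = "severe"
        else:
            slope = (row.t75 - row.t25) / row.tmed
            warns["slope"] = _grade(slope, config["slope"], low_is_bad=False)
    return warns


def roi_table_frame(rows: Sequence[ROITableRow]) -> pd.DataFrame:
    """The ROI table as a DataFrame (for TSV output and report rendering)."""
    return pd.DataFrame(
        [
            {
                "label": r.label, "Nvox": r.nvox, "Nzer": r.nzer, "Dvox": r.dvox,
                "Tmin": r.tmin, "T25": r.t25, "Tmed": r.tmed,
                "T75": r.t75, "Tmax": r.tmax,
                "peak_i": r.peak_ijk[0], "peak_j": r.peak_ijk[1],
                "peak_k": r.peak_ijk[2],
                "peak_x": r.peak_xyz[0], "peak_y": r.peak_xyz[1],
                "peak_z": r.peak_xyz[2],
            }
            for r in rows
        ]
    )


def mask_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|) of two binary masks on one grid.

    Two empty masks are defined to overlap perfectly (1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
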