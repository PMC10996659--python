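"""Motion-derived series, outlier fractions and censor construction.

The per-volume motion magnitude is the Euclidean norm of the forward
differences of the six rigid-body parameters ("enorm"), with degrees and
millimetres combined unweighted and the first volume of every run set to
zero (runs are acquired separately, so no cross-run difference exists).

The per-volume outlier fraction counts, within a brain mask, the voxels
whose detrended value at that time point is a temporal outlier of their
own series, judged against a robust MAD-based threshold.  Volumes where
either quantity exceeds its limit are censored; optionally the preceding
volume of an enorm-triggered event is censored too, since the motion
happened *between* the two volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_io import MotionParams, ReviewDict, VolumeSeries
from .quality_maps import detrend_poly

__all__ = [
    "CensorVector",
    "CensorSummary",
    "compute_enorm",
    "outlier_fractions",
    "make_censor",
    "censor_summary",
    "censor_review_entries",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd for normal data


@dataclass
class CensorVector:
    """Length-T keep/censor indicator with per-index provenance.

    ``keep[t]`` is 1 to keep volume t, 0 to censor it.  ``reasons`` maps
    each censored index to which limit fired: ``enorm``, ``outlier``,
    ``both``, or ``neighbor`` (pre-motion volume censored by the
    neighbor rule).
    """

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)
    enorm_limit: Optional[float] = None
    outlier_limit: Optional[float] = None

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep).astype(int)
        for t in np.flatnonzero(self.keep == 0):
            if int(t) not in self.reasons:
                raise ValueError(f"censored index {t} has no reason")

    @property
    def n_total(self) -> int:
        return int(self.keep.size)

    @property
    def n_censored(self) -> int:
        return int(np.count_nonzero(self.keep == 0))

    @property
    def fraction(self) -> float:
        return self.n_censored / self.n_total

    def censored_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep == 0)


@dataclass
class CensorSummary:
    """Counts plus before/after-censoring five-number summaries of a series."""

    n_total: int
    n_censored: int
    fraction: float
    per_run_fractions: list[float]
    bc: tuple[float, float, float, float, float]
    ac: Optional[tuple[float, float, float, float, float]]
    ac_empty: bool = False


def _run_starts(n_t: int, run_lengths: Sequence[int] | None) -> np.ndarray:
    if run_lengths is None:
        run_lengths = [n_t]
    if sum(run_lengths) != n_t:
        raise ValueError(f"run lengths {list(run_lengths)} do not sum to {n_t}")
    return np.cumsum([0] + list(run_lengths))[:-1]


def compute_enorm(
    mp: MotionParams | np.ndarray, run_lengths: Sequence[int] | None = None
) -> np.ndarray:
    """Euclidean norm of forward differences of the six motion parameters.

    ``enorm[t] = sqrt(sum_i (p[t,i] - p[t-1,i])^2)``; the first element of
    each run is 0.  Rotations (deg) and translations (mm) are combined
    without weighting.
    """
    values = mp.values if isinstance(mp, MotionParams) else np.asarray(mp, float)
    if values.ndim != 2 or values.shape[1] != 6:
        raise ValueError(f"expected a T x 6 motion table, got {values.shape}")
    n_t = values.shape[0]
    enorm = np.zeros(n_t)
    enorm[1:] = np.sqrt((np.diff(values, axis=0) ** 2).sum(axis=1))
    enorm[_run_starts(n_t, run_lengths)] = 0.0
    return enorm


def outlier_fractions(
    vol: VolumeSeries, mask: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Per-volume fraction of in-mask voxels that are temporal outliers.

    For each voxel the linear (per-run) trend is removed; a time point is
    an outlier when |residual| > k * 1.4826 * MAD(residual), with k the
    upper-tail standard-normal quantile at alpha/2.  Returns a length-T
    series in [0, 1].
    """
    mask_b = np.asarray(mask).astype(bool)
    if mask_b.shape != vol.shape3d:
        raise ValueError("mask grid mismatch")
    if not mask_b.any():
        raise ValueError("mask is empty")
    if vol.n_t < 4:
        raise ValueError("need at least 4 time points for outlier detection")
    rows = vol.data[mask_b]
    resid = detrend_poly(rows, 1, vol.run_lengths)
    med = np.median(resid, axis=1, keepdims=True)
    mad = np.median(np.abs(resid - med), axis=1, keepdims=True)
    k = stats.norm.isf(alpha / 2.0)
    thresh = k * MAD_SCALE * mad
    is_out = np.abs(resid) > thresh
    # a voxel whose residual spread is at numerical-noise scale has no
    # outliers (otherwise constant series would trip on rounding error)
    scale = np.abs(rows).mean(axis=1, keepdims=True) + 1.0
    is_out &= mad > 1e-12 * scale
    return is_out.mean(axis=0)


def make_censor(
    enorm: np.ndarray,
    outliers: np.ndarray,
    enorm_limit: float = 0.3,
    outlier_limit: float = 0.1,
    censor_prev: bool = True,
    run_lengths: Sequence[int] | None = None,
) -> CensorVector:
    """Censor volumes with suprathreshold enorm or outlier-fraction values.

    Index t is censored when ``enorm[t] > enorm_limit`` or
    ``outliers[t] > outlier_limit``.  With ``censor_prev``, the preceding
    volume of each enorm-triggered index (within the same run) is also
    censored with reason ``neighbor``.
    """
    enorm = np.asarray(enorm, dtype=float)
    outliers = np.asarray(outliers, dtype=float)
    if enorm.shape != outliers.shape:
        raise ValueError("enorm and outlier series lengths differ")
    if enorm_limit <= 0 or outlier_limit <= 0:
        raise ValueError("censor limits must be positive")
    n_t = enorm.size
    starts = set(int(s) for s in _run_starts(n_t, run_lengths))

    keep = np.ones(n_t, dtype=int)
    reasons: dict[int, str] = {}
    bad_en = enorm > enorm_limit
    bad_out = outliers > outlier_limit
    for t in range(n_t):
        if bad_en[t] and bad_out[t]:
            reasons[t] = "both"
        elif bad_en[t]:
            reasons[t] = "enorm"
        elif bad_out[t]:
            reasons[t] = "outlier"
        else:
            continue
        keep[t] = 0
    if censor_prev:
        for t in np.flatnonzero(bad_en):
            prev = int(t) - 1
            if prev >= 0 and int(t) not in starts and keep[prev] == 1:
                keep[prev] = 0
                reasons[prev] = "neighbor"
    return CensorVector(
        keep=keep, reasons=reasons,
        enorm_limit=enorm_limit, outlier_limit=outlier_limit,
    )


def _five_number(x: np.ndarray) -> tuple[float, float, float, float, float]:
    q = np.percentile(x, [0, 25, 50, 75, 100])
    return tuple(float(v) for v in q)


def censor_summary(
    series: np.ndarray,
    censor: CensorVector,
    run_lengths: Sequence[int] | None = None,
) -> CensorSummary:
    """Counts and BC/AC (before/after censoring) five-number summaries.

    BC summarizes the whole series; AC only the kept time points (flagged
    empty when everything is censored).  Per-run censored fractions use
    ``run_lengths`` (a single run by default).
    """
    series = np.asarray(series, dtype=float)
    if series.size != censor.n_total:
        raise ValueError("series and censor lengths differ")
    n_t = series.size
    if run_lengths is None:
        run_lengths = [n_t]
    starts = np.cumsum([0] + list(run_lengths))
    if starts[-1] != n_t:
        raise ValueError("run lengths do not sum to series length")
    per_run = [
        float(np.count_nonzero(censor.keep[a:b] == 0) / (b - a))
        for a, b in zip(starts[:-1], starts[1:])
    ]
    kept = series[censor.keep == 1]
    return CensorSummary(
        n_total=n_t,
        n_censored=censor.n_censored,
        fraction=censor.fraction,
        per_run_fractions=per_run,
        bc=_five_number(series),
        ac=_five_number(kept) if kept.size else None,
        ac_empty=kept.size == 0,
    )


def censor_review_entries(
    censor: CensorVector, run_lengths: Sequence[int] | None = None
) -> ReviewDict:
    """Review-dictionary entries for a censor vector.

    Rounding mirrors the printed review file: "censor fraction" to 6
    decimals, "fraction censored per run" to 7.
    """
    n_t = censor.n_total
    if run_lengths is None:
        run_lengths = [n_t]
    summ = censor_summary(np.zeros(n_t), censor, run_lengths)
    per_run = [round(f, 7) for f in summ.per_run_fractions]
    rd = ReviewDict()
    rd["num runs found"] = len(run_lengths)
    rd["num TRs per run"] = (
        list(map(float, run_lengths)) if len(run_lengths) > 1 else int(run_lengths[0])
    )
    rd["TRs total (uncensored)"] = n_t
    rd["TRs total"] = n_t - censor.n_censored
    rd["TRs censored"] = censor.n_censored
    rd["censor fraction"] = round(censor.fraction, 6)
    rd["fraction censored per run"] = per_run if len(per_run) > 1 else per_run[0]
    return rd
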