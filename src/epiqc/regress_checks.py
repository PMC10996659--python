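"""Degrees-of-freedom accounting and regression-model sanity checks.

Every regressor, every censored time point and every frequency bin
removed by bandpassing costs one degree of freedom (DF) out of the
``n_total`` time points of the series.  The :class:`DFLedger` tracks that
budget; :func:`bandpass_df` prices a band-pass in DFT-bin units (interior
bins cost 2 DFs — a sine and a cosine — while the DC and Nyquist bins
cost 1).  The classic "LFF" band of 0.01-0.1 Hz removes roughly 64% of
the DFs at TR = 2 s and over 80% at TR = 1 s, which is why the ledger is
worth watching.

Also here: pairwise-correlation / condition-number collinearity warnings
for the design matrix, per-stimulus censored-response fractions, and a
pre-steady-state detector for elevated initial volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_io import ReviewDict, VolumeSeries
from .motion_censor import CensorVector

__all__ = [
    "DFLedger",
    "DesignMatrix",
    "bandpass_df",
    "df_ledger",
    "collinearity_check",
    "stim_censor_fraction",
    "pre_steady_check",
]


@dataclass
class DesignMatrix:
    """T x P regressor matrix with labels and per-column group tags."""

    columns: np.ndarray
    labels: list[str]
    groups: list[str]  # per column: baseline | motion | interest

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("design matrix labels must be unique")
        if len(self.groups) != len(self.labels):
            raise ValueError("group tags must match columns")
        bad = set(self.groups) - {"baseline", "motion", "interest"}
        if bad:
            raise ValueError(f"unknown group tags {bad}")

    @property
    def n_t(self) -> int:
        return self.columns.shape[0]

    @property
    def n_p(self) -> int:
        return self.columns.shape[1]

    def count(self, group: str) -> int:
        return sum(g == group for g in self.groups)


@dataclass
class DFLedger:
    """Budget of degrees of freedom used vs left in the regression.

    ``df_used`` counts everything that consumes a DF: censored time
    points plus drift, motion, bandpass and other regressors.  (The
    printed review file's "degrees of freedom used" line counts only the
    regressors; :meth:`review_entries` follows that convention.)
    """

    n_total: int
    n_censored: int
    df_drift: int = 0
    df_motion: int = 0
    df_bandpass: int = 0
    df_other: int = 0
    severe: bool = field(default=False)

    @property
    def df_regressors(self) -> int:
        return self.df_drift + self.df_motion + self.df_bandpass + self.df_other

    @property
    def df_used(self) -> int:
        return self.n_censored + self.df_regressors

    @property
    def df_left(self) -> int:
        return self.n_total - self.df_used

    @property
    def frac_left(self) -> float:
        return self.df_left / self.n_total

    def review_entries(self) -> ReviewDict:
        rd = ReviewDict()
        rd["degrees of freedom used"] = self.df_regressors
        rd["degrees of freedom left"] = self.df_left
        rd["final DF fraction"] = round(self.frac_left, 6)
        return rd


def bandpass_df(
    n_t: int, tr_s: float, f_low_hz: float, f_high_hz: float
) -> dict:
    """DF cost of keeping only the [f_low, f_high] band of an n-point series.

    DFT frequency bins are k/(n*tr) for k = 0..floor(n/2).  Bins outside
    the band are projected out: interior bins cost 2 DFs each, the k=0
    (DC) and — for even n — Nyquist bins cost 1.  Returns
    ``{"df_removed": int, "frac_removed": float}``.
    """
    if n_t < 2:
        raise ValueError("need at least 2 time points")
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= f_low_hz < f_high_hz):
        raise ValueError("need 0 <= f_low < f_high")
    if f_high_hz > nyquist * (1 + 1e-12):
        raise ValueError(f"f_high {f_high_hz} exceeds Nyquist {nyquist}")
    removed = 0
    for k in range(n_t // 2 + 1):
        f = k / (n_t * tr_s)
        cost = 1 if (k == 0 or (n_t % 2 == 0 and k == n_t // 2)) else 2
        if not (f_low_hz <= f <= f_high_hz):
            removed += cost
    return {"df_removed": removed, "frac_removed": removed / n_t}


def df_ledger(
    n_total: int,
    censor: CensorVector | int,
    design: Optional[DesignMatrix] = None,
    bandpass: Optional[tuple[float, float, float]] = None,
    df_drift: int = 0,
    df_motion: int = 0,
    df_other: int = 0,
) -> DFLedger:
    """Assemble the DF ledger from censoring, design and bandpass choices.

    ``censor`` may be a :class:`CensorVector` or a plain censored count.
    Regressor DFs come from ``design`` group counts when given, else from
    the explicit ``df_*`` counts.  ``bandpass`` is (f_low, f_high, tr_s).
    A negative remainder is flagged ``severe`` rather than raised.
    """
    if isinstance(censor, CensorVector):
        if censor.n_total != n_total:
            raise ValueError("censor length does not match n_total")
        n_censored = censor.n_censored
    else:
        n_censored = int(censor)
        if n_censored < 0 or n_censored > n_total:
            raise ValueError("censored count out of range")
    if design is not None:
        df_drift = design.count("baseline")
        df_motion = design.count("motion")
        df_other = design.count("interest")
    df_bp = 0
    if bandpass is not None:
        f_low, f_high, tr_s = bandpass
        df_bp = bandpass_df(n_total, tr_s, f_low, f_high)["df_removed"]
    ledger = DFLedger(
        n_total=n_total,
        n_censored=n_censored,
        df_drift=df_drift,
        df_motion=df_motion,
        df_bandpass=df_bp,
        df_other=df_other,
    )
    ledger.severe = ledger.df_left < 0
    return ledger


DEFAULT_COLLIN_THRESH = (0.4, 0.6, 0.8)  # mild, medium, severe on |r|


def collinearity_check(
    design: DesignMatrix,
    censor: Optional[CensorVector] = None,
    thresholds: Sequence[float] = DEFAULT_COLLIN_THRESH,
    cond_severe: float = 1e8,
) -> list[dict]:
    """Pairwise-correlation and conditioning warnings for a design matrix.

    Correlations are computed between mean-removed columns over the kept
    time points only (all points when no censor is given).  Warnings are
    graded mild/medium/severe at |r| >= the configured thresholds.  The
    condition number of the column-normalized matrix is always reported,
    severe when numerically rank-deficient.
    """
    if design.n_t <= design.n_p:
        raise ValueError("need more time points than regressors")
    mild, medium, severe = thresholds
    cols = design.columns
    if censor is not None:
        if censor.n_total != design.n_t:
            raise ValueError("censor length does not match design")
        cols = cols[censor.keep == 1]

    warnings: list[dict] = []
    centered = cols - cols.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    usable = norms > 0
    for j in np.flatnonzero(~usable):
        warnings.append(
            {"kind": "zero_variance", "labels": (design.labels[j],),
             "value": 0.0, "level": "medium"}
        )
    idx = np.flatnonzero(usable)
    for a_pos, j in enumerate(idx):
        for k in idx[a_pos + 1:]:
            r = float(centered[:, j] @ centered[:, k] / (norms[j] * norms[k]))
            level = None
            if abs(r) >= severe:
                level = "severe"
            elif abs(r) >= medium:
                level = "medium"
            elif abs(r) >= mild:
                level = "mild"
            if level:
                warnings.append(
                    {"kind": "pair",
                     "labels": (design.labels[j], design.labels[k]),
                     "value": r, "level": level}
                )
    # conditioning of the unit-normalized matrix
    normed = cols.copy()
    col_norms = np.linalg.norm(normed, axis=0)
    nonzero = col_norms > 0
    normed[:, nonzero] /= col_norms[nonzero]
    cond = float(np.linalg.cond(normed[:, nonzero])) if nonzero.any() else np.inf
    deficient = (
        not nonzero.all()
        or np.linalg.matrix_rank(normed[:, nonzero]) < int(nonzero.sum())
        or cond > cond_severe
    )
    warnings.append(
        {"kind": "cond", "labels": (), "value": cond,
         "level": "severe" if deficient else "none"}
    )
    return warnings


def stim_censor_fraction(
    ideal: np.ndarray, censor: CensorVector
) -> list[dict]:
    """Per-stimulus censored fraction of the response interval.

    The response set of a stimulus is the time points where its idealized
    response regressor is nonzero; the fraction is censored-within-
    response over response size, rounded to 3 decimals for reporting.
    An all-zero regressor yields ``fraction None`` with a flag.
    """
    ideal = np.atleast_2d(np.asarray(ideal, dtype=float))
    if ideal.shape[0] == 1 and ideal.shape[1] == censor.n_total:
        ideal = ideal.T
    if ideal.shape[0] != censor.n_total:
        raise ValueError("ideal regressor length does not match censor")
    out = []
    censored = censor.keep == 0
    for s in range(ideal.shape[1]):
        resp = np.abs(ideal[:, s]) > 0
        n_resp = int(resp.sum())
        if n_resp == 0:
            out.append(
                {"stim": s, "n_resp": 0, "n_censored": 0,
                 "fraction": None, "undefined": True}
            )
            continue
        n_cens = int(np.count_nonzero(resp & censored))
        out.append(
            {"stim": s, "n_resp": n_resp, "n_censored": n_cens,
             "fraction": round(n_cens / n_resp, 3), "undefined": False}
        )
    return out


def pre_steady_check(
    vol: VolumeSeries,
    mask: np.ndarray,
    rel_excess: float = 0.02,
    max_check: int = 4,
) -> list[list[int]]:
    """Flag elevated pre-steady-state volumes at the start of each run.

    For each run, leading volumes whose mask-mean intensity strictly
    exceeds (1 + rel_excess) times the run's median mask-mean are
    flagged, scanning from the run start up to the first non-flagged
    volume and at most ``max_check`` volumes.  Returns per-run lists of
    global time indices (empty when steady).
    """
    mask_b = np.asarray(mask).astype(bool)
    if mask_b.shape != vol.shape3d:
        raise ValueError("mask grid mismatch")
    means = vol.data[mask_b].mean(axis=0)
    flagged: list[list[int]] = []
    for sl in vol.run_slices():
        run = means[sl]
        limit = (1.0 + rel_excess) * np.median(run)
        hits = []
        for i in range(min(max_check, run.size)):
            if run[i] > limit:
                hits.append(sl.start + i)
            else:
                break
        flagged.append(hits)
    return flagged
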