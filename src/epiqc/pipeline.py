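"""End-to-end single-subject QC: metrics -> blocks -> report directory.

``run_subject`` wires the per-module computations together in the order
a report reads: raw-data checks (vorig), motion/censoring (mot),
regression numerics (regr), radial correlation (radcor), artifact
warnings (warns) and the quantitative summary (qsumm).  Everything is
deterministic given identical inputs, so rerunning into a fresh
directory reproduces it byte for byte.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import motion_censor as mc
from . import quality_maps as qm
from . import regress_checks as rc
from .artifact_checks import (
    DEFAULT_WARN_LEVELS,
    WarnLevel,
    aggregate_warns,
    data_range_check,
    flip_check,
    variance_lines,
)
from .data_io import MotionParams, ReviewDict, VolumeSeries
from .report import QCBlock, build_report, render_montage

__all__ = ["run_subject"]


def _grayplot_png(gp: qm.GrayplotMatrix, path: Path) -> None:
    n_strips = int(gp.motion is not None) + int(gp.outliers is not None)
    fig, axes = plt.subplots(
        1 + n_strips, 1, figsize=(6, 3 + 0.5 * n_strips),
        gridspec_kw={"height_ratios": [1] * n_strips + [5]}, squeeze=False,
    )
    row = 0
    for series, label in ((gp.motion, "enorm"), (gp.outliers, "outliers")):
        if series is None:
            continue
        ax = axes[row][0]
        ax.plot(series, lw=0.6, color="k")
        ax.set_ylabel(label, fontsize=6)
        ax.set_xticks([])
        row += 1
    ax = axes[row][0]
    ax.imshow(
        gp.values, aspect="auto", cmap="gray",
        vmin=-gp.clip, vmax=gp.clip, interpolation="nearest",
    )
    ax.set_xlabel("time (TR)")
    ax.set_ylabel("voxels (similarity order)")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def run_subject(
    vol: VolumeSeries,
    anat: Optional[VolumeSeries] = None,
    mask: Optional[np.ndarray] = None,
    motion: Optional[np.ndarray] = None,
    ideal: Optional[np.ndarray] = None,
    subject: str = "subj",
    outdir: str | Path = "QC",
    enorm_limit: float = 0.3,
    outlier_limit: float = 0.1,
) -> Path:
    """Compute the QC battery for one subject and write the report."""
    outdir = Path(outdir)
    media = outdir / "media"
    media.mkdir(parents=True, exist_ok=True)
    if mask is None:
        peak = float(np.abs(vol.data).max())
        mask = np.abs(vol.data).mean(axis=3) > 0.1 * peak
    mask = np.asarray(mask).astype(bool)

    review = ReviewDict()
    review["subject ID"] = subject
    review["num TRs per run"] = (
        list(map(float, vol.run_lengths))
        if len(vol.run_lengths) > 1 else int(vol.run_lengths[0])
    )
    review["TR"] = vol.tr
    blocks: list[QCBlock] = []

    # ----- vorig: raw data checks -----------------------------------------
    vorig = QCBlock("vorig", "vorig: original EPI data")
    rng_check = data_range_check(vol)
    vorig.add_text(
        f"stored data range: [{rng_check['min']:.6g}, {rng_check['max']:.6g}]"
        + (f"  flags: {', '.join(rng_check['flags'])}" if rng_check["flags"] else "")
    )
    meta = render_montage(
        vol.data[..., 0], plane="axial", n_slices=6,
        path=media / "vorig_epi.png", title="EPI volume 0",
    )
    vorig.add_image(meta["path"], "first EPI volume")
    vorig_warns = [
        WarnLevel(DEFAULT_WARN_LEVELS[f], f) for f in rng_check["flags"]
    ]
    vorig.warn = aggregate_warns(vorig_warns)
    review["min stored value"] = rng_check["min"]
    review["max stored value"] = rng_check["max"]
    blocks.append(vorig)

    # ----- mot: motion, outliers, censoring -------------------------------
    enorm = None
    censor = None
    outliers = mc.outlier_fractions(vol, mask)
    if motion is not None:
        mp = motion if isinstance(motion, MotionParams) else MotionParams(motion)
        enorm = mc.compute_enorm(mp, vol.run_lengths)
        censor = mc.make_censor(
            enorm, outliers, enorm_limit, outlier_limit,
            censor_prev=True, run_lengths=vol.run_lengths,
        )
        review.update(mc.censor_review_entries(censor, vol.run_lengths))
        summ = mc.censor_summary(enorm, censor, vol.run_lengths)
        review["average motion (per TR)"] = round(float(np.mean(enorm)), 6)
        review["max motion displacement"] = round(float(np.max(enorm)), 6)

        mot = QCBlock("mot", "mot: subject motion and censoring")
        fig, axes = plt.subplots(2, 1, figsize=(6, 3), sharex=True)
        axes[0].plot(enorm, lw=0.8)
        axes[0].axhline(enorm_limit, color="r", lw=0.5)
        axes[0].set_ylabel("enorm")
        axes[1].plot(outliers, lw=0.8)
        axes[1].axhline(outlier_limit, color="r", lw=0.5)
        axes[1].set_ylabel("outlier frac")
        for t in censor.censored_indices():
            for ax in axes:
                ax.axvspan(t - 0.5, t + 0.5, color="r", alpha=0.3, lw=0)
        fig.tight_layout()
        fig.savefig(media / "mot_series.png", dpi=100, metadata={"Software": None})
        plt.close(fig)
        mot.add_image(media / "mot_series.png", "enorm and outlier fraction")
        mot.add_text(
            f"censored {censor.n_censored}/{censor.n_total} volumes "
            f"(fraction {summ.fraction:.6f})"
        )
        gp = qm.grayplot(vol, mask, motion=enorm, outliers=outliers)
        _grayplot_png(gp, media / "mot_grayplot.png")
        mot.add_image(media / "mot_grayplot.png", "grayplot (carpet plot)")
        blocks.append(mot)

    # ----- regr: TSNR, GCOR, corr_brain, DF ledger ------------------------
    regr = QCBlock("regr", "regr: regression and modeling information")
    tsnr = qm.tsnr_volreg(vol, mask)
    review["TSNR average"] = round(tsnr.extras["tsnr_average"], 2)
    g = qm.gcor(vol, mask)
    review["global correlation (GCOR)"] = round(g, 7)
    resid_rows = qm.detrend_poly(vol.data[mask], 2, vol.run_lengths)
    resid = np.zeros_like(vol.data)
    resid[mask] = resid_rows
    errts = VolumeSeries(
        resid, vol.voxdims, vol.tr, vol.orient, list(vol.run_lengths), vol.affine
    )
    cb = qm.corr_brain(errts, mask)
    meta = render_montage(
        vol.data[..., 0], overlay=tsnr, plane="axial", n_slices=6,
        path=media / "regr_tsnr.png", title="TSNR (volreg stage)",
    )
    regr.add_image(meta["path"], "TSNR map")
    meta = render_montage(
        vol.data[..., 0], overlay=cb, plane="axial", n_slices=6,
        path=media / "regr_corr_brain.png", thr=0.3, vmax=0.6,
        title="corr_brain",
    )
    regr.add_image(meta["path"], "corr_brain map")
    if censor is not None:
        ledger = rc.df_ledger(vol.n_t, censor)
        review.update(ledger.review_entries())
    if ideal is not None and censor is not None:
        stim = rc.stim_censor_fraction(np.asarray(ideal), censor)
        review["num TRs per stim (orig)"] = (
            [float(s["n_resp"]) for s in stim] if len(stim) > 1
            else stim[0]["n_resp"]
        )
        fracs = [s["fraction"] if s["fraction"] is not None else -1.0 for s in stim]
        review["fraction TRs censored"] = fracs if len(fracs) > 1 else fracs[0]
    blocks.append(regr)

    # ----- radcor ----------------------------------------------------------
    radcor_block = QCBlock("radcor", "radcor: radial correlation")
    rad = qm.radial_correlate(vol, mask)
    meta = render_montage(
        vol.data[..., 0], overlay=rad, plane="axial", n_slices=6,
        path=media / "radcor.png", thr=0.5, vmax=1.0, title="radial correlation",
    )
    radcor_block.add_image(meta["path"], "radcor map")
    blocks.append(radcor_block)

    # ----- warns ------------------------------------------------------------
    warns_block = QCBlock("warns", "warns: internal checks")
    warn_levels: list[WarnLevel] = []
    try:
        lines = variance_lines(
            vol, mask, keep=None if censor is None else censor.keep
        )
    except ValueError:
        lines = None
    if lines is not None:
        if len(lines):
            warns_block.add_table(lines, "variance line table")
            warn_levels.append(
                WarnLevel(DEFAULT_WARN_LEVELS["variance_lines_any"],
                          f"{len(lines)} variance line(s)")
            )
            lines.to_csv(outdir / "variance_lines.tsv", sep="\t", index=False)
        else:
            warns_block.add_text("no variance lines detected")
    pre = rc.pre_steady_check(vol, mask)
    n_pre = sum(len(r) for r in pre)
    if n_pre:
        warns_block.add_text(f"pre-steady-state volumes flagged: {pre}")
        warn_levels.append(
            WarnLevel(DEFAULT_WARN_LEVELS["pre_steady_any"],
                      f"{n_pre} pre-steady-state volume(s)")
        )
    review["num pre-steady-state TRs"] = n_pre
    if anat is not None:
        fc = flip_check(
            vol.data[..., 0], anat.data[..., 0], mask, orient=vol.orient
        )
        review["flip guess"] = fc["guess"]
        warns_block.add_text(
            f"flip check: cost as-is {fc['cost_asis']:.4f}, "
            f"flipped {fc['cost_flipped']:.4f} -> {fc['guess']}"
        )
        warn_levels.append(
            WarnLevel(DEFAULT_WARN_LEVELS[f"flip_{fc['guess']}"]
                      if fc["guess"] != "ambiguous"
                      else DEFAULT_WARN_LEVELS["flip_ambiguous"], "flip check")
        )
    warns_block.warn = aggregate_warns(warn_levels)
    blocks.append(warns_block)

    return build_report(blocks, review=review, outdir=outdir, subject=subject)
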