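"""Static HTML QC report assembly, display mathematics and ratings.

A report is an ordered sequence of QC blocks (vorig, vstat, mot, regr,
radcor, warns, qsumm, ...), each holding images, tables and text plus a
warning level.  ``build_report`` writes a self-contained directory — one
``index.html``, a ``media/`` subdirectory and JSON sidecars — with a top
menu whose block labels carry the block's maximum warning color.  The
directory has no network resources and can be moved between machines.

Ratings ("+" good, "x" bad, "?" other, "" unrated) and free-text
comments per block (plus an overall "FINAL") persist in a JSON file in
the QC directory; saving a comment on an unrated block automatically
applies the "other" rating.

Display-math helpers mirror the conventions used for statistic overlays:
colorbar maxima at the 99th and thresholds at the 90th percentile of
|values| in the brain mask, sub-threshold opacity falling quadratically
("alpha" transparent thresholding), and two-sided t thresholds at
p = 0.001.
"""

from __future__ import annotations

import html
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .artifact_checks import WarnLevel
from .data_io import ReviewDict, write_review
from .quality_maps import StatVolume

__all__ = [
    "QCBlock",
    "RatingStore",
    "percentile_range",
    "alpha_opacity",
    "two_sided_t_threshold",
    "render_montage",
    "build_report",
    "ratings_io",
]

BLOCK_ORDER = ("vorig", "vstat", "mot", "regr", "radcor", "warns", "qsumm")

WARN_COLORS = {
    "none": "#0f0",
    "undecided": "#ff0",
    "mild": "#fbb",
    "medium": "#f66",
    "severe": "#f00",
}

RATING_CYCLE = ("+", "x", "?")


@dataclass
class QCBlock:
    """One titled section of the QC page."""

    id: str
    title: str
    items: list[dict] = field(default_factory=list)
    warn: WarnLevel = field(default_factory=lambda: WarnLevel("none"))

    def add_image(self, path: str | Path, caption: str = "") -> None:
        self.items.append({"type": "image", "path": str(path), "caption": caption})

    def add_table(self, frame, caption: str = "", cell_levels=None) -> None:
        self.items.append(
            {"type": "table", "frame": frame, "caption": caption,
             "cell_levels": cell_levels}
        )

    def add_text(self, text: str) -> None:
        self.items.append({"type": "text", "text": text})


# ---------------------------------------------------------------------------
# display mathematics
# ---------------------------------------------------------------------------

def percentile_range(stat: StatVolume | np.ndarray, mask: np.ndarray) -> dict:
    """Overlay display range: threshold = p90, max = p99 of in-mask |values|.

    Percentiles use linear interpolation.  A degenerate all-zero map is
    flagged so renderers can fall back to a plain underlay.
    """
    data = stat.data if isinstance(stat, StatVolume) else np.asarray(stat, float)
    mask_b = np.asarray(mask).astype(bool)
    if not mask_b.any():
        raise ValueError("mask is empty")
    vals = np.abs(data[mask_b])
    thr = float(np.percentile(vals, 90))
    vmax = float(np.percentile(vals, 99))
    return {"thr": thr, "vmax": vmax, "degenerate": vmax == 0.0}


def alpha_opacity(v: np.ndarray | float, thr: float):
    """Transparent-threshold opacity: 1 above threshold, (|v|/thr)^2 below."""
    if thr <= 0:
        raise ValueError("threshold must be positive")
    a = np.minimum(np.abs(np.asarray(v, dtype=float)) / thr, 1.0) ** 2
    if np.isscalar(v) or np.asarray(v).ndim == 0:
        return float(a)
    return a


def two_sided_t_threshold(df: float, p: float = 0.001) -> float:
    """The t value with two-sided tail mass p at the given df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return float(stats.t.isf(p / 2.0, df))


# ---------------------------------------------------------------------------
# montages
# ---------------------------------------------------------------------------

_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


def _automask(underlay: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Light automask of the FOV: voxels above frac * max intensity."""
    peak = np.max(np.abs(underlay))
    if peak == 0:
        return np.zeros(underlay.shape, dtype=bool)
    return np.abs(underlay) > frac * peak


def montage_slice_indices(
    underlay: np.ndarray, plane: str = "axial", n_slices: int = 6
) -> list[int]:
    """Evenly spaced slice indices within the automask's bounding range.

    With an empty automask the full axis range is used; a single
    requested slice lands on the range midpoint.
    """
    axis = _PLANE_AXIS[plane]
    am = _automask(underlay)
    if am.any():
        occupied = np.flatnonzero(am.any(axis=tuple(i for i in range(3) if i != axis)))
        lo, hi = int(occupied[0]), int(occupied[-1])
    else:
        lo, hi = 0, underlay.shape[axis] - 1
    if n_slices == 1:
        return [int(round((lo + hi) / 2))]
    return sorted(set(int(round(v)) for v in np.linspace(lo, hi, n_slices)))


def render_montage(
    underlay: np.ndarray,
    overlay: Optional[StatVolume] = None,
    plane: str = "axial",
    n_slices: int = 6,
    path: str | Path = "montage.png",
    thr: Optional[float] = None,
    vmax: Optional[float] = None,
    title: str = "",
) -> dict:
    """Render an n-slice montage, optionally alpha-compositing an overlay.

    Slice positions come from :func:`montage_slice_indices`.  Overlay
    voxels get opacity from :func:`alpha_opacity` and suprathreshold
    regions are outlined ("boxed") with a contour at the threshold.
    Returns metadata including the slice indices used.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}")
    underlay = np.asarray(underlay, dtype=float)
    idx = montage_slice_indices(underlay, plane, n_slices)
    axis = _PLANE_AXIS[plane]

    over = overlay.data if overlay is not None else None
    if over is not None:
        rng = percentile_range(overlay, np.ones(underlay.shape, dtype=bool))
        if vmax is None:
            vmax = rng["vmax"] if rng["vmax"] > 0 else 1.0
        if thr is None:
            thr = rng["thr"] if rng["thr"] > 0 else vmax / 2.0

    fig, axes = plt.subplots(
        1, len(idx), figsize=(2.0 * len(idx), 2.2), squeeze=False
    )
    for ax, k in zip(axes[0], idx):
        sl = np.take(underlay, k, axis=axis).T
        ax.imshow(sl, cmap="gray", origin="lower", interpolation="nearest")
        if over is not None:
            osl = np.take(over, k, axis=axis).T
            alpha = alpha_opacity(osl, thr)
            ax.imshow(
                osl, cmap="RdYlBu_r", origin="lower", interpolation="nearest",
                vmin=-vmax, vmax=vmax, alpha=alpha,
            )
            if np.any(np.abs(osl) >= thr):
                ax.contour(
                    np.abs(osl), levels=[thr], colors="black", linewidths=0.6
                )
        ax.set_title(f"{plane[0]}={k}", fontsize=7)
        ax.axis("off")
    if title:
        fig.suptitle(title, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return {"path": str(path), "slices": idx, "thr": thr, "vmax": vmax}


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

class RatingStore:
    """Per-block QC ratings ("+", "x", "?", "") and comments, plus FINAL.

    Invariant: a nonempty comment always has a nonempty rating (saving a
    comment on an unrated block auto-applies "?").
    """

    def __init__(self, block_ids: Sequence[str]):
        ids = list(block_ids)
        if "FINAL" not in ids:
            ids.append("FINAL")
        self._entries = {bid: {"rating": "", "comment": ""} for bid in ids}

    @property
    def block_ids(self) -> list[str]:
        return list(self._entries)

    def _check(self, block_id: str) -> None:
        if block_id not in self._entries:
            raise KeyError(f"unknown block id {block_id!r}")

    def get(self, block_id: str) -> dict:
        self._check(block_id)
        return dict(self._entries[block_id])

    def set_rating(self, block_id: str, rating: str | None = None,
                   cycle: bool = False) -> None:
        self._check(block_id)
        entry = self._entries[block_id]
        if cycle:
            cur = entry["rating"]
            nxt = RATING_CYCLE[(RATING_CYCLE.index(cur) + 1) % len(RATING_CYCLE)] \
                if cur in RATING_CYCLE else RATING_CYCLE[0]
            entry["rating"] = nxt
            return
        if rating is None:
            raise ValueError("rating required when not cycling")
        rating = "x" if rating == "×" else rating
        if rating not in ("+", "x", "?", ""):
            raise ValueError(f"invalid rating {rating!r}")
        if rating == "" and entry["comment"]:
            entry["comment"] = ""  # clearing the rating clears the comment too
        entry["rating"] = rating

    def set_comment(self, block_id: str, comment: str) -> None:
        self._check(block_id)
        entry = self._entries[block_id]
        entry["comment"] = comment
        if comment and not entry["rating"]:
            entry["rating"] = "?"  # auto-"other" on commenting an unrated block

    def clear(self, block_id: str) -> None:
        self._check(block_id)
        self._entries[block_id] = {"rating": "", "comment": ""}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self._entries, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RatingStore":
        raw = json.loads(Path(path).read_text())
        store = cls(list(raw))
        for bid, entry in raw.items():
            rating = entry.get("rating", "")
            rating = "x" if rating == "×" else rating
            comment = entry.get("comment", "")
            store._entries[bid] = {"rating": "", "comment": ""}
            if rating:
                store.set_rating(bid, rating)
            if comment:
                store.set_comment(bid, comment)
        return store

    def to_dict(self) -> dict:
        return {bid: dict(e) for bid, e in self._entries.items()}


def ratings_io(store: RatingStore, action: str, **args) -> RatingStore:
    """Functional dispatcher over :class:`RatingStore` actions.

    Actions: ``set_rating`` (block, rating or cycle=True), ``set_comment``
    (block, comment), ``clear`` (block), ``save`` (path), ``load`` (path,
    classmethod-style: store may be None).
    """
    if action == "set_rating":
        store.set_rating(args["block"], args.get("rating"), args.get("cycle", False))
    elif action == "set_comment":
        store.set_comment(args["block"], args["comment"])
    elif action == "clear":
        store.clear(args["block"])
    elif action == "save":
        store.save(args["path"])
    elif action == "load":
        return RatingStore.load(args["path"])
    else:
        raise ValueError(f"unknown action {action!r}")
    return store


# ---------------------------------------------------------------------------
# HTML assembly
# ---------------------------------------------------------------------------

_CSS = """
body { background: #111; color: #ddd; font-family: sans-serif; margin: 0; }
#menu { position: sticky; top: 0; background: #000; padding: 6px;
        border-bottom: 1px solid #444; }
#menu a { margin-right: 12px; text-decoration: none; font-weight: bold; }
section { padding: 10px 16px; border-bottom: 1px solid #333; }
h2 { color: gold; }
table { border-collapse: collapse; }
td, th { border: 1px solid #555; padding: 2px 8px; font-size: 13px; }
img { max-width: 100%; }
.warn-severe { color: #000; background: #f00; padding: 0 4px; }
.warn-medium { color: #000; background: #f66; padding: 0 4px; }
.warn-mild { color: #fbb; }
.warn-undecided { color: #ff0; }
.warn-none { color: #0f0; }
"""


def _menu_class(level: str) -> str:
    return f"warn-{level}"


def _render_table(frame, cell_levels=None) -> str:
    cols = list(frame.columns)
    parts = ["<table>", "<tr>" + "".join(f"<th>{html.escape(str(c))}</th>" for c in cols) + "</tr>"]
    for i, (_, row) in enumerate(frame.iterrows()):
        cells = []
        for c in cols:
            val = row[c]
            txt = f"{val:.4g}" if isinstance(val, float) else str(val)
            level = None
            if cell_levels is not None:
                level = cell_levels[i].get(str(c)) if i < len(cell_levels) else None
            cls = f' class="warn-{level}"' if level and level != "none" else ""
            cells.append(f"<td{cls}>{html.escape(txt)}</td>")
        parts.append("<tr>" + "".join(cells) + "</tr>")
    parts.append("</table>")
    return "\n".join(parts)


def build_report(
    blocks: Sequence[QCBlock],
    review: Optional[ReviewDict] = None,
    outdir: str | Path = "QC",
    subject: str = "subj",
    fixed_clock: bool = True,
) -> Path:
    """Assemble QC blocks into a self-contained report directory.

    Writes ``index.html`` plus ``media/`` (images copied in), the initial
    ratings JSON ``apqc_{subject}.rate.json`` and, when a review
    dictionary is supplied, a ``qsumm`` block rendering it verbatim and a
    group-tools copy under ``extra_info/out.ss_review.{subject}.json``.
    With ``fixed_clock`` (default) no timestamps are embedded, so
    rebuilding from identical inputs is byte-identical.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one QC block")
    ids = [b.id for b in blocks]
    if len(ids) != len(set(ids)):
        raise ValueError("QC block ids must be unique")

    outdir = Path(outdir)
    media = outdir / "media"
    media.mkdir(parents=True, exist_ok=True)

    if review is not None and "qsumm" not in ids:
        qsumm = QCBlock(id="qsumm", title="qsumm: quantitative summary")
        blocks.append(qsumm)
        ids.append("qsumm")

    # order known blocks canonically, extras after, preserving given order
    rank = {bid: i for i, bid in enumerate(BLOCK_ORDER)}
    blocks.sort(key=lambda b: (rank.get(b.id, len(BLOCK_ORDER)), ids.index(b.id)))

    menu_links = []
    sections = []
    for block in blocks:
        menu_links.append(
            f'<a href="#{block.id}" class="{_menu_class(block.warn.level)}">'
            f"{html.escape(block.id)}</a>"
        )
        body = []
        for item in block.items:
            if item["type"] == "image":
                src = Path(item["path"])
                dest = media / src.name
                if src.resolve() != dest.resolve():
                    shutil.copyfile(src, dest)
                body.append(f'<img src="media/{html.escape(src.name)}" alt="">')
                if item.get("caption"):
                    body.append(f"<p>{html.escape(item['caption'])}</p>")
            elif item["type"] == "table":
                if item.get("caption"):
                    body.append(f"<p>{html.escape(item['caption'])}</p>")
                body.append(_render_table(item["frame"], item.get("cell_levels")))
            elif item["type"] == "text":
                body.append(f"<p>{html.escape(item['text'])}</p>")
        if block.id == "qsumm" and review is not None:
            rows = []
            for label, value in review.items():
                if isinstance(value, (list, tuple)):
                    value = " ".join(str(v) for v in value)
                rows.append(
                    f"<tr><td>{html.escape(str(label))}</td>"
                    f"<td>{html.escape(str(value))}</td></tr>"
                )
            body.append("<table>" + "".join(rows) + "</table>")
        warn_txt = (
            f'<span class="{_menu_class(block.warn.level)}">'
            f"{block.warn.level}</span>"
        )
        sections.append(
            f'<section id="{block.id}"><h2>{html.escape(block.title)}</h2>'
            f"<p>warning level: {warn_txt}"
            + (f" — {html.escape(block.warn.message)}" if block.warn.message else "")
            + "</p>"
            + "\n".join(body)
            + "</section>"
        )

    stamp = "" if fixed_clock else "<!-- built without fixed clock -->"
    page = (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        f"<title>QC: {html.escape(subject)}</title>"
        f"<style>{_CSS}</style></head>\n<body>\n"
        f'<div id="menu">RATE | {" ".join(menu_links)} | FINAL</div>\n'
        + "\n".join(sections)
        + f"\n{stamp}</body></html>\n"
    )
    (outdir / "index.html").write_text(page)

    store = RatingStore([b.id for b in blocks])
    rate_path = outdir / f"apqc_{subject}.rate.json"
    if not rate_path.exists():  # keep any previously saved ratings
        store.save(rate_path)

    if review is not None:
        extra = outdir / "extra_info"
        extra.mkdir(exist_ok=True)
        write_review(review, extra / f"out.ss_review.{subject}.json", format="json")
    return outdir
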