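"""Cross-subject tabulation and filtering of review dictionaries.

``build_group_table`` stacks per-subject review files (colon text or
JSON) into one table — rows are subjects, columns the union of labels in
first-seen order, cells typed number/string/vector/missing.  Filters
mirror the review-table query grammar:

* ``VARY`` — the value differs from the first subject's;
* ``EQ`` — equals an operand (string or numeric);
* ``GT``/``LT``/``GE``/``LE`` — numeric comparisons.

A subject is flagged when any filter fires; vector cells flag when ANY
element satisfies the comparison (so one bad per-stimulus fraction is
enough).  ``-show_keepers`` semantics invert the flagged set.  Missing
cells never satisfy ordered comparisons or EQ, while VARY treats missing
as differing — missing data should surface, not hide.

``gtkyd_scan`` ("getting to know your data") collects basic header and
intensity properties per raw dataset and runs a VARY report over every
property, surfacing protocol inconsistencies before any processing.
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .data_io import ReviewDict, read_review, write_review

__all__ = [
    "GroupTable",
    "FilterSpec",
    "build_group_table",
    "parse_filter",
    "report_outliers",
    "gtkyd_scan",
]

logger = logging.getLogger(__name__)

MISSING = None

VALID_OPS = ("VARY", "EQ", "GT", "LT", "GE", "LE")


@dataclass
class GroupTable:
    """Subjects x labels table of review values."""

    subjects: list[str]
    columns: list[str]
    cells: dict  # (subject, label) -> value

    def value(self, subject: str, label: str):
        return self.cells.get((subject, label), MISSING)

    def to_frame(self) -> pd.DataFrame:
        data = {
            col: [self._cell_text(self.value(s, col)) for s in self.subjects]
            for col in self.columns
        }
        return pd.DataFrame(data, index=self.subjects)

    @staticmethod
    def _cell_text(v) -> str:
        if v is MISSING:
            return ""
        if isinstance(v, (list, tuple)):
            return " ".join(str(x) for x in v)
        return str(v)

    def write(self, path: str | Path, sep: str = "\t") -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "subject"
        frame.to_csv(path, sep=sep)
        return path


@dataclass
class FilterSpec:
    """One outlier query: label, operator, operand, optional SHOW columns."""

    label: str
    op: str
    operand: Optional[str] = None
    show_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.op not in VALID_OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        if self.op != "VARY" and self.operand is None:
            raise ValueError(f"operator {self.op} requires an operand")


def parse_filter(text: str) -> FilterSpec:
    """Parse a quoted query string: ``'censor fraction' GE 0.1 SHOW 'TSNR average'``."""
    tokens = shlex.split(text)
    if len(tokens) < 2:
        raise ValueError(f"cannot parse filter {text!r}")
    label, op = tokens[0], tokens[1].upper()
    rest = tokens[2:]
    operand = None
    if op != "VARY":
        if not rest:
            raise ValueError(f"operator {op} requires an operand in {text!r}")
        operand, rest = rest[0], rest[1:]
    show = []
    while rest:
        if rest[0].upper() == "SHOW":
            rest = rest[1:]
            continue
        show.append(rest[0])
        rest = rest[1:]
    return FilterSpec(label=label, op=op, operand=operand, show_labels=show)


def build_group_table(paths: Sequence[str | Path]) -> GroupTable:
    """Stack review files into a group table (union of labels).

    The subject id is the "subject ID" entry when present, else the file
    stem.  Unreadable files raise unless at least nothing is readable.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one review file")
    subjects: list[str] = []
    columns: list[str] = []
    cells: dict = {}
    n_read = 0
    for path in paths:
        try:
            rd = read_review(path)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable review file %s: %s", path, exc)
            continue
        n_read += 1
        sid = str(rd.get("subject ID", path.stem))
        if sid in subjects:
            sid = f"{sid}:{path.stem}"
        subjects.append(sid)
        for label, value in rd.items():
            if label not in columns:
                columns.append(label)
            cells[(sid, label)] = value
    if n_read == 0:
        raise ValueError("no readable review files")
    return GroupTable(subjects=subjects, columns=columns, cells=cells)


def _as_float(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _eq(value, operand: str) -> bool:
    a, b = _as_float(value), _as_float(operand)
    if a is not None and b is not None:
        if a == b:
            return True
        scale = max(abs(a), abs(b))
        return scale > 0 and abs(a - b) <= 1e-9 * scale
    return str(value) == str(operand)


def _compare_scalar(value, op: str, operand: str) -> bool:
    if op == "EQ":
        return _eq(value, operand)
    a, b = _as_float(value), _as_float(operand)
    if a is None or b is None:
        logger.warning("skipping non-numeric comparison %r %s %r", value, op, operand)
        return False
    return {"GT": a > b, "LT": a < b, "GE": a >= b, "LE": a <= b}[op]


def _values_differ(a, b) -> bool:
    if isinstance(a, (list, tuple)) or isinstance(b, (list, tuple)):
        return list(np.atleast_1d(a)) != list(np.atleast_1d(b))
    fa, fb = _as_float(a), _as_float(b)
    if fa is not None and fb is not None:
        return fa != fb
    return str(a) != str(b)


def filter_fires(value, spec: FilterSpec, reference=None) -> bool:
    """Does one cell satisfy one query?  Missing cells only fire for VARY."""
    if spec.op == "VARY":
        if value is MISSING and reference is MISSING:
            return False
        if value is MISSING or reference is MISSING:
            return True
        return _values_differ(value, reference)
    if value is MISSING:
        return False
    if isinstance(value, (list, tuple)):
        return any(_compare_scalar(v, spec.op, spec.operand) for v in value)
    return _compare_scalar(value, spec.op, spec.operand)


def report_outliers(
    table: GroupTable,
    filters: Sequence[FilterSpec | str],
    keepers: bool = False,
) -> pd.DataFrame:
    """Subtable of subjects flagged by one or more queries.

    Columns: the queried labels (values shown for fired queries) plus any
    SHOW labels.  ``keepers`` inverts the subject set — those with *no*
    firing query.
    """
    specs = [parse_filter(f) if isinstance(f, str) else f for f in filters]
    first = table.subjects[0] if table.subjects else None
    fired: dict[str, dict[str, object]] = {}
    for subject in table.subjects:
        hits = {}
        for spec in specs:
            ref = table.value(first, spec.label) if spec.op == "VARY" else None
            if filter_fires(table.value(subject, spec.label), spec, ref):
                hits[spec.label] = table.value(subject, spec.label)
        if hits:
            fired[subject] = hits

    selected = (
        [s for s in table.subjects if s not in fired]
        if keepers
        else [s for s in table.subjects if s in fired]
    )
    cols: list[str] = []
    for spec in specs:
        for label in [spec.label] + spec.show_labels:
            if label not in cols:
                cols.append(label)
    rows = {}
    for subject in selected:
        rows[subject] = {
            c: GroupTable._cell_text(table.value(subject, c)) for c in cols
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    frame.index.name = "subject"
    return frame


# ---------------------------------------------------------------------------
# gtkyd: raw-dataset property scan
# ---------------------------------------------------------------------------

GTKYD_PROPERTIES = (
    "ni", "nj", "nk", "n_time", "voxel_dx", "voxel_dy", "voxel_dz",
    "TR", "datum", "orientation", "min_stored", "max_stored",
    "has_slice_timing", "saturation_flag",
)


def _dataset_properties(path: Path) -> ReviewDict:
    img = nib.load(str(path))
    hdr = img.header
    shape = img.shape
    zooms = hdr.get_zooms()
    unscaled = np.asanyarray(img.dataobj.get_unscaled())
    smin, smax = float(unscaled.min()), float(unscaled.max())
    try:
        slice_dur = float(hdr.get_slice_duration())
    except Exception:  # slice dimension unset: no slice timing recorded
        slice_dur = 0.0
    slice_timed = bool(slice_dur > 0 or int(hdr.get("slice_code", 0) or 0) > 0)
    rd = ReviewDict()
    rd["subject ID"] = path.name.split(".")[0]
    rd["ni"], rd["nj"], rd["nk"] = int(shape[0]), int(shape[1]), int(shape[2])
    rd["n_time"] = int(shape[3]) if len(shape) > 3 else 1
    rd["voxel_dx"], rd["voxel_dy"], rd["voxel_dz"] = (
        round(float(zooms[0]), 6), round(float(zooms[1]), 6), round(float(zooms[2]), 6)
    )
    rd["TR"] = round(float(zooms[3]), 6) if len(shape) > 3 else 0.0
    rd["datum"] = str(hdr.get_data_dtype())
    rd["orientation"] = "".join(nib.aff2axcodes(img.affine))
    rd["min_stored"] = smin
    rd["max_stored"] = smax
    rd["has_slice_timing"] = "yes" if slice_timed else "no"
    rd["saturation_flag"] = "yes" if smax == 4095 else "no"
    return rd


def gtkyd_scan(
    paths: Sequence[str | Path],
    outdir: Optional[str | Path] = None,
) -> tuple[list[ReviewDict], pd.DataFrame]:
    """Basic-property dictionaries per dataset plus a variability report.

    Properties: matrix dims, voxel sizes, TR, time points, datum type,
    orientation, stored min/max, slice-timing presence and the 4095
    saturation flag.  The variability report is ``report_outliers`` with
    VARY on every property.  Unreadable datasets are skipped with a log
    entry.  When ``outdir`` is given, per-dataset dict files and
    ``variability.tsv`` are written there.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one dataset path")
    dicts: list[ReviewDict] = []
    read_paths: list[Path] = []
    for path in sorted(paths, key=lambda p: str(p)):
        try:
            dicts.append(_dataset_properties(path))
            read_paths.append(path)
        except Exception as exc:
            logger.warning("skipping unreadable dataset %s: %s", path, exc)
    if not dicts:
        raise ValueError("no readable datasets")

    subjects: list[str] = []
    for rd, path in zip(dicts, read_paths):
        sid = str(rd["subject ID"])
        if sid in subjects:  # same file name in different directories
            sid = f"{path.parent.name}/{sid}"
            rd["subject ID"] = sid
        subjects.append(sid)
    columns: list[str] = []
    cells: dict = {}
    for sid, rd in zip(subjects, dicts):
        for label, value in rd.items():
            if label == "subject ID":
                continue
            if label not in columns:
                columns.append(label)
            cells[(sid, label)] = value
    table = GroupTable(subjects=subjects, columns=columns, cells=cells)
    varying = report_outliers(
        table, [FilterSpec(label=c, op="VARY") for c in GTKYD_PROPERTIES if c in columns]
    )
    # keep only the columns that actually vary somewhere
    keep_cols = [
        c for c in varying.columns
        if any(
            filter_fires(
                table.value(s, c), FilterSpec(label=c, op="VARY"),
                table.value(subjects[0], c),
            )
            for s in subjects
        )
    ]
    varying = varying[keep_cols]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, rd in zip(subjects, dicts):
            safe = sid.replace("/", "_")
            write_review(rd, outdir / f"gtkyd.{safe}.txt", format="colon")
        varying.to_csv(outdir / "variability.tsv", sep="\t")
    return dicts, varying
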