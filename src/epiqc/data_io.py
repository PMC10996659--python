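"""Readers and writers for the formats the QC toolkit touches.

Four families of files move through the toolkit:

* 4D EPI time series and 3D anatomical/mask/atlas volumes (NIfTI-1,
  ``.nii``/``.nii.gz``), held in memory as :class:`VolumeSeries`;
* whitespace-separated numeric column text ("1D" files) for motion
  parameters, regressors and censor vectors;
* per-subject review dictionaries — ordered label -> value maps of QC
  quantities — stored either as colon-separated text or JSON
  (:class:`ReviewDict`);
* TSV tables for group-level output (written through pandas elsewhere).

Coordinate convention: voxel indices are 0-based everywhere; world (mm)
coordinates only ever come from the NIfTI affine.  No resampling is done
anywhere in the toolkit — paired volumes must already share a grid.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeSeries",
    "MotionParams",
    "ReviewDict",
    "read_volume4d",
    "write_volume4d",
    "read_table_1d",
    "write_table_1d",
    "read_review",
    "write_review",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """A 4D intensity array plus the grid metadata QC calculations need.

    ``data`` is (x, y, z, t) with the NIfTI scale factors already applied.
    ``stored_min``/``stored_max`` keep the raw on-disk extrema so that
    intensity checks (negative values, 12-bit saturation at 4095) see the
    stored units even after scaling.
    """

    data: np.ndarray
    voxdims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 0.0
    orient: str = "RAS"
    run_lengths: list[int] = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    stored_min: float = 0.0
    stored_max: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if any(v <= 0 for v in self.voxdims):
            raise ValueError(f"voxel dimensions must be positive: {self.voxdims}")
        if not self.run_lengths:
            self.run_lengths = [self.n_t]
        if any(r <= 0 for r in self.run_lengths):
            raise ValueError("run lengths must be positive")
        if sum(self.run_lengths) != self.n_t:
            raise ValueError(
                f"run lengths {self.run_lengths} do not sum to t={self.n_t}"
            )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_t(self) -> int:
        return self.data.shape[3]

    def run_slices(self) -> list[slice]:
        """Per-run time slices, in order."""
        out, start = [], 0
        for n in self.run_lengths:
            out.append(slice(start, start + n))
            start += n
        return out


@dataclass
class MotionParams:
    """T x 6 rigid-body motion estimates.

    Column order follows the volume-registration convention: roll, pitch,
    yaw in degrees, then dS, dL, dP translations in mm.
    """

    values: np.ndarray

    COLUMNS = ("roll", "pitch", "yaw", "dS", "dL", "dP")

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ValueError(
                f"motion table must have exactly 6 columns, got {self.values.shape[1]}"
            )

    @property
    def n_t(self) -> int:
        return self.values.shape[0]


class ReviewDict(dict):
    """Ordered label -> value map of QC quantities.

    Values are numbers, strings, or lists of numbers.  Insertion order is
    preserved (plain ``dict`` semantics) and round-trips through both the
    colon-separated text format and JSON.
    """

    def copy(self) -> "ReviewDict":
        return ReviewDict(self)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume4d(
    path: str | Path,
    tr: float | None = None,
    run_lengths: Sequence[int] | None = None,
) -> VolumeSeries:
    """Load a 3D or 4D NIfTI volume as a :class:`VolumeSeries`.

    A 3D input becomes a t=1 series.  TR is taken from the header (pixdim
    of the 4th axis) unless ``tr`` overrides it.  NIfTI scl_slope/scl_inter
    are applied to ``data``; the raw stored extrema are kept alongside.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various ImageFileErrors
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    ndim = len(img.shape)
    if ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3 or 4 dimensions, got {ndim}")

    data = np.asarray(img.get_fdata(dtype=np.float64))
    unscaled = np.asanyarray(img.dataobj.get_unscaled())
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if ndim == 4 else 0.0
    n_t = data.shape[3] if ndim == 4 else 1
    return VolumeSeries(
        data=data,
        voxdims=tuple(float(z) for z in zooms[:3]),
        tr=float(tr) if tr is not None else header_tr,
        orient="".join(nib.aff2axcodes(img.affine)),
        run_lengths=list(run_lengths) if run_lengths else [n_t],
        affine=np.asarray(img.affine, dtype=float),
        stored_min=float(np.min(unscaled)),
        stored_max=float(np.max(unscaled)),
    )


def write_volume4d(vol: VolumeSeries, path: str | Path, dtype=np.float32) -> Path:
    """Write a :class:`VolumeSeries` (or its squeezed 3D form) to NIfTI-1."""
    path = Path(path)
    data = vol.data
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), vol.affine)
    zooms = list(vol.voxdims) + ([vol.tr] if data.ndim == 4 else [])
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# 1D column text
# ---------------------------------------------------------------------------

def read_table_1d(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated numeric table; ``#`` lines are comments.

    Returns a 2D (rows x columns) float array.  Ragged rows and
    non-numeric tokens are rejected.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncol: int | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric token in {tokens!r}") from exc
        if ncol is None:
            ncol = len(values)
        elif len(values) != ncol:
            raise ValueError(
                f"{path}:{lineno}: inconsistent column count "
                f"({len(values)} vs {ncol})"
            )
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    return np.array(rows, dtype=float)


def write_table_1d(
    values: np.ndarray, path: str | Path, comments: Sequence[str] = ()
) -> Path:
    """Write a numeric table in 1D column-text form."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and np.asarray(values).ndim == 1:
        arr = arr.T
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for row in arr:
            fh.write(" ".join(_fmt_number(v) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# review dictionaries
# ---------------------------------------------------------------------------

_INT_RE = re.compile(r"[+-]?\d+$")


def _parse_value(text: str):
    """Colon-format value parsing: fully numeric -> number(s), else verbatim."""
    tokens = text.split()
    if not tokens:
        return ""
    parsed = []
    for tok in tokens:
        if _INT_RE.match(tok):
            parsed.append(int(tok))
        else:
            try:
                parsed.append(float(tok))
            except ValueError:
                return text  # mixed/non-numeric: keep the whole value verbatim
    if len(parsed) == 1:
        return parsed[0]
    return [float(p) for p in parsed]


def _fmt_number(v) -> str:
    if isinstance(v, (int, np.integer)) and not isinstance(v, bool):
        return str(int(v))
    # repr of a Python float is the shortest round-trippable form
    return repr(float(v))


def _fmt_value(v) -> str:
    if isinstance(v, str):
        return v
    if isinstance(v, (list, tuple, np.ndarray)):
        return " ".join(_fmt_number(x) for x in v)
    return _fmt_number(v)


def read_review(path: str | Path) -> ReviewDict:
    """Read a review dictionary from colon-separated text or JSON.

    The format is auto-detected.  Colon lines look like
    ``TSNR average : 191.52``; values of several numeric tokens become
    vectors and anything not fully numeric stays a verbatim string.
    Duplicate labels are an error in either format.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        def _no_dups(pairs):
            rd = ReviewDict()
            for k, v in pairs:
                if k in rd:
                    raise ValueError(f"{path}: duplicate label {k!r}")
                rd[k] = v
            return rd

        return json.loads(text, object_pairs_hook=_no_dups)

    rd = ReviewDict()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: unparseable line {line!r}")
        label, _, value = line.partition(":")
        label = label.strip()
        if not label:
            raise ValueError(f"{path}:{lineno}: empty label")
        if label in rd:
            raise ValueError(f"{path}:{lineno}: duplicate label {label!r}")
        rd[label] = _parse_value(value.strip())
    return rd


def write_review(rd: ReviewDict, path: str | Path, format: str = "colon") -> Path:
    """Write a review dictionary; ``read_review`` round-trips the result.

    Colon format prints one ``label : value`` line per entry, vectors
    space-separated; floats use their shortest round-trippable repr
    (always >= 6 significant digits of the stored value).
    """
    path = Path(path)
    if format == "colon":
        lines = [f"{label} : {_fmt_value(v)}" for label, v in rd.items()]
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        def _default(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"cannot serialize {type(o)}")

        path.write_text(json.dumps(rd, indent=2, default=_default) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'colon' or 'json')")
    return path
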