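"""Deterministic EPI phantom generator with ground-truth records.

The phantom emulates the signal and artifact structure the QC detectors
are built for, on a desk-scale grid (default 24 x 24 x 16 voxels, 3 mm
isotropic, TR 2 s, 200 volumes):

* an ellipsoidal "brain" of baseline intensity with per-run polynomial
  drift and i.i.d. Gaussian noise, plus a dim asymmetric parietal blob so
  left and right are distinguishable;
* optional block-design activation (percent signal change in a planted
  region, with the matching boxcar ideal regressors);
* motion spikes realized **both** as single-volume steps in the motion
  parameter table and as integer-voxel in-plane shifts of the affected
  volumes, so the censoring truth and the image effect agree exactly;
* through-plane variance lines (amplified noise over whole (i, j)
  columns), a "bad coil" patch (one latent series added to an octant),
  a shared global-signal component, elevated pre-steady-state initial
  volumes, and optional left-right mirroring of the EPI.

Identical spec + seed produce byte-identical outputs.  Every injected
artifact is echoed back in the :class:`TruthRecord` so detector tests
can compare against construction rather than against themselves.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .data_io import (
    MotionParams,
    VolumeSeries,
    write_table_1d,
    write_volume4d,
)

__all__ = [
    "PhantomSpec",
    "TruthRecord",
    "Phantom",
    "make_phantom",
    "write_fixture_bundle",
]


@dataclass
class PhantomSpec:
    """Full description of one phantom, JSON-serializable."""

    dims: tuple[int, int, int] = (24, 24, 16)
    voxdims: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0
    run_lengths: list[int] = field(default_factory=lambda: [200])
    baseline: float = 1000.0
    noise_sd: float = 10.0
    drift_coeffs: list[float] = field(default_factory=lambda: [0.0, 0.01])
    brain_axes_frac: tuple[float, float, float] = (0.42, 0.42, 0.42)
    seed: int = 0
    # artifacts (all optional)
    motion_spikes: Optional[dict] = None       # {"times": [...], "magnitudes": [...]}
    variance_lines: Optional[list[dict]] = None  # [{"ij": [i, j], "gain": g}, ...]
    coil_patch: Optional[dict] = None          # {"octant": 0..7, "sd": s}
    global_signal: Optional[dict] = None       # {"sd": s}
    task: Optional[dict] = None                # {"onsets","durations","effect_pct"}
    presteady: Optional[dict] = None           # {"n": n, "excess": e}
    lr_flip: bool = False

    @property
    def n_t(self) -> int:
        return sum(self.run_lengths)

    def validate(self) -> None:
        if any(d < 4 for d in self.dims):
            raise ValueError("grid too small")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.motion_spikes:
            if any(t >= self.n_t or t < 1 for t in self.motion_spikes["times"]):
                raise ValueError("motion spike times out of range")
        if self.variance_lines:
            for line in self.variance_lines:
                i, j = line["ij"]
                if not (0 <= i < self.dims[0] and 0 <= j < self.dims[1]):
                    raise ValueError(f"variance line {line['ij']} outside plane")
        if self.task:
            for onset, dur in zip(self.task["onsets"], self.task["durations"]):
                if onset + dur > self.n_t:
                    raise ValueError("task block extends past the series")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("dims", "voxdims", "brain_axes_frac"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthRecord:
    """Ground truth for every injected artifact, for detector tests."""

    mask: np.ndarray
    expected_censor: list[int]
    spike_times: list[int]
    line_ij: list[tuple[int, int]]
    coil_voxels: Optional[np.ndarray]
    task_voxels: Optional[np.ndarray]
    presteady_indices: list[int]
    lr_flip: bool
    shared_variance_frac: float

    def to_json_dict(self) -> dict:
        return {
            "expected_censor": [int(t) for t in self.expected_censor],
            "spike_times": [int(t) for t in self.spike_times],
            "line_ij": [[int(i), int(j)] for i, j in self.line_ij],
            "n_coil_voxels": 0 if self.coil_voxels is None else int(self.coil_voxels.sum()),
            "n_task_voxels": 0 if self.task_voxels is None else int(self.task_voxels.sum()),
            "presteady_indices": [int(t) for t in self.presteady_indices],
            "lr_flip": bool(self.lr_flip),
            "shared_variance_frac": float(self.shared_variance_frac),
        }


@dataclass
class Phantom:
    """Everything one phantom emits."""

    vol: VolumeSeries
    anat: VolumeSeries
    mask: np.ndarray
    motion: MotionParams
    ideal: Optional[np.ndarray]  # T x S boxcar regressors
    truth: TruthRecord
    spec: PhantomSpec


def _ellipsoid(dims, axes_frac) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    center = [(d - 1) / 2.0 for d in dims]
    axes = [max(f * d, 1.0) for f, d in zip(axes_frac, dims)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def _expected_censor(
    spec: PhantomSpec,
    enorm_limit: float = 0.3,
    censor_prev: bool = True,
) -> list[int]:
    """Censored indices implied by the spike parameters and default limits.

    A single-volume displacement of magnitude m at time t makes the
    forward-difference norm equal m at both t and t+1 (where those are
    not run boundaries); the neighbor rule adds the volume before each
    suprathreshold one.
    """
    if not spec.motion_spikes:
        return []
    starts = np.cumsum([0] + list(spec.run_lengths))[:-1]
    start_set = set(int(s) for s in starts)
    run_of = np.concatenate(
        [np.full(n, i) for i, n in enumerate(spec.run_lengths)]
    )
    over: set[int] = set()
    for t, m in zip(spec.motion_spikes["times"], spec.motion_spikes["magnitudes"]):
        if abs(m) <= enorm_limit:
            continue
        if t not in start_set:
            over.add(int(t))
        nxt = int(t) + 1
        if nxt < spec.n_t and nxt not in start_set and run_of[nxt] == run_of[t]:
            over.add(nxt)
    censored = set(over)
    if censor_prev:
        for t in over:
            prev = t - 1
            if prev >= 0 and t not in start_set:
                censored.add(prev)
    return sorted(censored)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Realize a phantom from its spec; reproducible from spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    n_t = spec.n_t

    mask = _ellipsoid(spec.dims, spec.brain_axes_frac)

    # spatial baseline: brain intensity with a smooth interior gradient and
    # a dim asymmetric blob on the +x side so left/right are distinguishable
    base = np.where(mask, spec.baseline, 0.02 * spec.baseline)
    xg, yg, zg = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    base = base * (1.0 + 0.08 * xg + 0.05 * yg - 0.04 * zg)
    blob = ((xg - 0.45) ** 2 + yg ** 2 + zg ** 2) < 0.12
    base = np.where(mask & blob, base * 1.30, base)

    # drift multiplies the baseline per run
    drift = np.empty(n_t)
    start = 0
    for n in spec.run_lengths:
        x = np.linspace(-1.0, 1.0, n)
        d = np.zeros(n)
        for p, c in enumerate(spec.drift_coeffs):
            d += c * x ** (p + 1)
        drift[start:start + n] = d
        start += n

    data = base[..., None] * (1.0 + drift)[None, None, None, :]
    data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    truth_coil = None
    truth_task = None
    ideal = None

    if spec.global_signal:
        s = rng.standard_normal(n_t)
        data[mask] += spec.global_signal["sd"] * s

    if spec.coil_patch:
        octant = int(spec.coil_patch["octant"])
        cx, cy, cz = nx // 2, ny // 2, nz // 2
        sel = np.zeros(spec.dims, dtype=bool)
        xs = slice(cx, nx) if octant & 1 else slice(0, cx)
        ys = slice(cy, ny) if octant & 2 else slice(0, cy)
        zs = slice(cz, nz) if octant & 4 else slice(0, cz)
        sel[xs, ys, zs] = True
        sel &= mask
        latent = rng.standard_normal(n_t)
        data[sel] += spec.coil_patch["sd"] * latent
        truth_coil = sel

    if spec.task:
        boxcar = np.zeros(n_t)
        for onset, dur in zip(spec.task["onsets"], spec.task["durations"]):
            boxcar[onset:onset + dur] = 1.0
        region = mask & (((xg + 0.3) ** 2 + (yg + 0.3) ** 2 + zg ** 2) < 0.15)
        amp = spec.task["effect_pct"] / 100.0
        data[region] += (base[region][:, None] * amp) * boxcar[None, :]
        ideal = boxcar[:, None]
        truth_task = region

    line_ij: list[tuple[int, int]] = []
    if spec.variance_lines:
        for line in spec.variance_lines:
            i, j = (int(v) for v in line["ij"])
            data[i, j, :, :] += rng.normal(
                0.0, line["gain"] * spec.noise_sd, size=(nz, n_t)
            )
            line_ij.append((i, j))

    presteady_idx: list[int] = []
    if spec.presteady:
        n_pre = int(spec.presteady["n"])
        excess = float(spec.presteady["excess"])
        start = 0
        for n in spec.run_lengths:
            for i in range(min(n_pre, n)):
                data[..., start + i] *= 1.0 + excess
                presteady_idx.append(start + i)
            start += n

    # motion: zero table except single-volume spikes; the affected volumes
    # are also shifted by an integer voxel count in-plane (no interpolation,
    # so the parameter truth and the image effect are exactly consistent)
    motion = np.zeros((n_t, 6))
    spike_times: list[int] = []
    if spec.motion_spikes:
        for t, m in zip(spec.motion_spikes["times"], spec.motion_spikes["magnitudes"]):
            t = int(t)
            motion[t, 4] = m  # dL translation, mm
            shift = max(1, int(round(abs(m) / spec.voxdims[0])))
            data[..., t] = np.roll(data[..., t], int(np.sign(m)) * shift, axis=0)
            spike_times.append(t)

    if spec.lr_flip:
        data = np.flip(data, axis=0).copy()

    affine = np.diag(list(spec.voxdims) + [1.0])
    vol = VolumeSeries(
        data=data, voxdims=spec.voxdims, tr=spec.tr, orient="RAS",
        run_lengths=list(spec.run_lengths), affine=affine,
        stored_min=float(data.min()), stored_max=float(data.max()),
    )

    # anatomical: same structures, different contrast and smoothness; never
    # mirrored (a flipped EPI must disagree with it)
    anat_data = ndimage.gaussian_filter(base, sigma=0.8) * 1.5
    anat_data = anat_data + rng.normal(0.0, 0.01 * spec.baseline, size=anat_data.shape)
    anat = VolumeSeries(
        data=anat_data, voxdims=spec.voxdims, tr=0.0, orient="RAS", affine=affine,
        stored_min=float(anat_data.min()), stored_max=float(anat_data.max()),
    )

    shared_frac = 0.0
    if spec.global_signal and spec.noise_sd > 0:
        g2 = spec.global_signal["sd"] ** 2
        shared_frac = g2 / (g2 + spec.noise_sd ** 2)

    truth = TruthRecord(
        mask=mask,
        expected_censor=_expected_censor(spec),
        spike_times=spike_times,
        line_ij=line_ij,
        coil_voxels=truth_coil,
        task_voxels=truth_task,
        presteady_indices=presteady_idx,
        lr_flip=spec.lr_flip,
        shared_variance_frac=shared_frac,
    )
    return Phantom(
        vol=vol, anat=anat, mask=mask,
        motion=MotionParams(motion), ideal=ideal, truth=truth, spec=spec,
    )


def write_fixture_bundle(phantom: Phantom, outdir: str | Path) -> Path:
    """Write one phantom as a directory every QC entry point can consume.

    Contents: ``epi.nii``, ``anat.nii``, ``mask.nii`` (uncompressed, so
    reruns are byte-identical), ``motion.1D``, optional ``ideal.1D``,
    ``truth.json`` and the generating ``spec.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume4d(phantom.vol, outdir / "epi.nii")
    write_volume4d(phantom.anat, outdir / "anat.nii")
    mask_vol = VolumeSeries(
        phantom.mask.astype(np.float32),
        phantom.spec.voxdims, 0.0, "RAS", affine=phantom.vol.affine,
    )
    write_volume4d(mask_vol, outdir / "mask.nii", dtype=np.uint8)
    write_table_1d(
        phantom.motion.values, outdir / "motion.1D",
        comments=["roll pitch yaw dS dL dP"],
    )
    if phantom.ideal is not None:
        write_table_1d(phantom.ideal, outdir / "ideal.1D", comments=["ideal responses"])
    payload = phantom.truth.to_json_dict()
    payload["run_lengths"] = list(phantom.spec.run_lengths)
    payload["tr"] = phantom.spec.tr
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
    phantom.spec.to_json(outdir / "spec.json")
    return outdir
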