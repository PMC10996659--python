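# epiqc

Quantitative quality control for FMRI EPI time series.

FMRI datasets fail in recurring, well-catalogued ways: subjects move,
scanner coils misbehave, intensity saturates, left and right get swapped
during conversion, and aggressive preprocessing silently spends the
degrees of freedom the statistics later need.  `epiqc` implements the
numerical core of a single-subject QC battery — the metrics, detectors
and report machinery — for 4D NIfTI EPI volumes and their motion
parameter tables, plus group-level tooling to triage those numbers
across subjects.  It is aimed at anyone processing EPI data who wants
systematic, scriptable checks: pipeline builders, curators of shared
data collections, and methodologists testing detectors against
synthetic ground truth.

## What it computes

**Motion and censoring.**  The per-volume motion magnitude is the
Euclidean norm of forward differences of the six rigid-body parameters,

&nbsp;&nbsp;enorm(t) = ‖p(t) − p(t−1)‖₂ ,

combining degrees and mm unweighted and resetting at run breaks.  The
outlier fraction counts in-mask voxels whose detrended value at time t
exceeds a robust threshold k·1.4826·MAD of their own series.  Volumes
with enorm > L₁ or outlier fraction > L₂ are censored (defaults 0.3 and
0.1), optionally together with the preceding volume.

**Quality maps.**  TSNR = mean(signal)/sd(noise) per voxel, at the
post-registration stage (noise = detrended series) or the
post-regression stage (noise = residuals).  GCOR is the average of all
pairwise temporal correlations over the mask, computed as ‖mean of unit
variance-normalized series‖².  corr_brain correlates each residual
series with the brain-average residual; radial correlation (radcor)
correlates each voxel with a Gaussian-weighted 20 mm FWHM neighborhood
average; the grayplot is the V×T matrix of Z-scored series, rows sorted
by similarity to the first principal component and clipped at the
two-sided normal p = 0.001 value (±3.2905).

**Regression checks.**  A degrees-of-freedom ledger (each censored
volume, regressor and removed frequency bin costs one DF; a 0.01–0.1 Hz
bandpass removes ~64% of DFs at TR = 2 s and ~82% at TR = 1 s), design
matrix collinearity warnings, per-stimulus censored-response fractions
and pre-steady-state detection.

**Artifact detectors.**  Left-right flip detection via the local Pearson
correlation cost between EPI and anatomical (as-is vs mirrored);
through-plane variance-line detection via in-plane neighborhood-ratio
scoring of column-wise temporal sd; raw intensity range flags (negative
values, 12-bit saturation at 4095); per-ROI TSNR/shape tables with
erosion-depth and graded warnings; Dice mask overlap.

**Reports and group tools.**  A self-contained static HTML report of QC
blocks (`vorig`, `mot`, `regr`, `radcor`, `warns`, `qsumm`) with
persisted per-block ratings and comments, group tables over review
dictionaries with `VARY/EQ/GT/LT/GE/LE` filtering, and a raw-dataset
property consistency scan (`gtkyd`).

**Phantoms.**  A deterministic generator injects every artifact class
the detectors target — motion spikes mirrored in the parameter table,
variance lines, a bad-coil patch, a shared global signal, pre-steady
volumes, left-right mirroring — and echoes exact ground truth, so all
detectors are testable offline.

## Worked example

```python
import numpy as np
from epiqc import (PhantomSpec, make_phantom, compute_enorm,
                   outlier_fractions, make_censor, gcor, bandpass_df)

spec = PhantomSpec(seed=13, run_lengths=[200],
                   motion_spikes={"times": [50, 51, 120],
                                  "magnitudes": [1.0, 1.0, 1.0]})
ph = make_phantom(spec)
enorm = compute_enorm(ph.motion, ph.vol.run_lengths)
outl = outlier_fractions(ph.vol, ph.mask)
censor = make_censor(enorm, outl, 0.3, 0.1, censor_prev=True)
print("censored:", [int(t) for t in censor.censored_indices()])
print("fraction: %.6f" % censor.fraction)
print("GCOR: %.4f" % gcor(ph.vol, ph.mask))
print("bandpass DF cost: %.1f%%" %
      (100 * bandpass_df(200, 2.0, 0.01, 0.1)["frac_removed"]))
```

prints

```
censored: [49, 50, 51, 52, 119, 120, 121]
fraction: 0.035000
GCOR: 0.0988
bandpass DF cost: 63.0%
```

The three planted motion spikes censor seven volumes: each
single-volume displacement makes enorm fire at the spike and the
following volume, and the neighbor rule adds the volume before (spikes
at 50 and 51 share boundaries, so their windows merge).  GCOR is small
but nonzero — the phantom's common drift term correlates all voxels
slightly.  Band-passing a 200-point TR = 2 s series to 0.01–0.1 Hz
discards 63% of its degrees of freedom.

From a shell, the same pipeline runs end to end:

```sh
qc-phantom --seed 13 --out bundle/
qc-run --bundle bundle/ --subject demo --out QC_demo/
qc-table -write_table group.tsv -infiles QC_demo/extra_info/*.json \
         -report_outliers "'censor fraction' GE 0.1"
```

`QC_demo/index.html` is the report; ratings persist in
`QC_demo/apqc_demo.rate.json`.

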