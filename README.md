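# igtplan

A hardware-free toolkit for real-time surgical-planning infrastructure and
pedicle-screw placement evaluation. It re-creates, as a plain Python
library, the software core of an augmented-reality planning setup in which
a headset-side planner and an image-computing server exchange OpenIGTLink
messages: the planner streams object poses (spine model, CT plane, screws)
as `TRANSFORM` messages, the server reslices a preloaded CT along the plane
pose and answers with a 100 × 100 uint8 `IMAGE`. On top of that exchange
sits the full placement-accuracy evaluation used to compare an AR planner
against a desktop planner — pedicle-waist reference geometry,
mediolateral/inferosuperior axis offsets, Gertzbein–Robbins grading, and
non-inferiority statistics — all exercisable end-to-end on procedurally
generated spine phantoms, with no scanner data, headset, or GUI.

It is intended for researchers building or benchmarking image-guided
planning pipelines who need the wire protocol, the reslicing geometry, or
the evaluation statistics as testable, scriptable components.

## What it computes

**Wire protocol.** Bit-exact OpenIGTLink `TRANSFORM`/`IMAGE` codec:
58-byte big-endian header, CRC-64/ECMA-182 body checksum (polynomial
`0x42F0E1EBA9EA3693`), 12-float transform body, 72-byte image sub-header,
and version-3 key/value metadata (used to tell the far side which model
file each transform belongs to). TCP client/server sessions and an
in-process loopback share one framing code path.

**Reslicing.** A volume grid with an index→world (RAS, mm) affine, loaded
from NIfTI or NRRD; pixel (u, v) of a slice samples the world point
`pose · ((u+½)·su − w/2, (v+½)·sv − h/2, 0)` by trilinear interpolation
(exact on affine fields), then maps through a window/level to uint8.

**Evaluation.** Each pedicle's reference point is the centre of its
minimum-diameter coronal cross-section (the "waist"): coronal slices are
scanned, the longest mediolateral and inferosuperior chords are measured,
and the waist minimises the smaller of the two. A screw's error is the
in-plane offset of its longitudinal axis from that centre,

```
error = sqrt(ml² + is²)   [mm, in the waist's coronal plane]
```

with lateral and superior positive. Grading follows the Gertzbein–Robbins
scale on maximum cortical breach depth of the screw cylinder (A = none,
B < 2 mm, C < 4 mm, D < 6 mm, E ≥ 6 mm); grades A–B count as successful.
Methods are compared by Mann–Whitney U (exact permutation enumeration for
n + m ≤ 12, tie-corrected normal approximation otherwise), Kruskal–Wallis,
and a one-sided 95 % lower Wald bound on the success-proportion difference
against a −10 percentage-point non-inferiority margin.

**Phantom.** Vertebrae are implicit solids — elliptic-cylinder body, two
pedicles with a parabolic waist (width 12.3 ± 0.8 mm, height 17.1 ± 1.0 mm,
lumbar population statistics) and a 10° medial convergence, a soft-tissue
canal — voxelized at 1 mm with exact analytic ground truth, so the entire
pipeline can be validated against known geometry.

## Worked example

`examples/04_evaluate_study.py` simulates six users instrumenting two
phantom spines with eight screws each (one spine per method, pairing
randomized per user), evaluates every screw through the mask-based
pipeline, and prints:

```
96 graded plans (6 users x 2 spines x 8 screws)

Method     Mean±SD (mm)   Median/IQR (mm)
AR         2.3 ± 1.0      2.3/1.5
desktop    1.3 ± 0.6      1.2/0.6

Method       A    B    C    D    E  % Success
AR          47    1    0    0    0       100
desktop     48    0    0    0    0       100

Mann-Whitney U on error: U=1842, p=0.000
Kruskal-Wallis across pedicles: p=0.293
Kruskal-Wallis across users:    p=0.571
non-inferiority lower bound (margin -10%): +0.053 -> non-inferior
```

The first table is the per-method placement error against the pedicle-waist
centres; the second tallies Gertzbein–Robbins grades and the A+B success
percentage. The desktop error distribution is tighter (that is how the two
simulated error models are configured), yet the AR arm's success proportion
stays within the margin, so the non-inferiority bound is positive. The
other examples demonstrate the wire codec (`01`), the reslice loopback and
frame-counting latency report (`02`), and scene mirroring over the wire
(`03`).

A command-line interface covers the same workflows from a shell:

```sh
igtplan phantom --levels 4 --spacing 1.0 --seed 7 --out phantom_out
igtplan serve-reslice --volume phantom_out/ct.nrrd --port 18944
igtplan latency --port 18944 --trials 30 --rate 120 --out latency.json
igtplan plan-sim --seed 1 --out study_out
igtplan report --records study_out/plans.csv --out report_out
```

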