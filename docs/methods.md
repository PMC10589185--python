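# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `igtplan`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Wire protocol

Messages follow the OpenIGTLink framing: a 58-byte big-endian header
(protocol version `u16`, type name `12s`, device name `20s`, timestamp as
32-bit seconds + 32-bit binary fraction, body size `u64`, body CRC `u64`)
followed by the body. The body checksum is CRC-64/ECMA-182 (polynomial
`0x42F0E1EBA9EA3693`, init 0, non-reflected, no final xor); the `b"123456789"`
check value `0x6C40DF5F0B497347` and a bit-by-bit long-division oracle pin
the implementation in tests.

Headers are emitted as version 2 by default. Attaching metadata switches
the message to the version-3 layout: a 12-byte extended header, the
content, then an index of `(key size, encoding, value size)` entries and
the raw key/value bytes. Both versions are accepted on decode; unknown
metadata keys are carried verbatim and never interpreted. The scene uses
the invented keys `ModelFileName`, `ObjectRole` (∈ spine/screw/plane),
`ScrewDiameterMm`, `ScrewLengthMm` — the last two exist so a mirror scene
can be reconstructed from the message stream alone.

The `TRANSFORM` body is 12 big-endian float32: rotation columns then
translation (mm). Decoding validates orthonormality at 1e-6; a rotation
that fails only because of float32 rounding is polished by SVD, but clean
matrices are left untouched so that decode→encode is byte-identical. The
`IMAGE` body carries a 72-byte sub-header (version, component count,
scalar type code, pixel endianness, coordinate frame, grid size, the three
axis vectors scaled by per-pixel spacing plus the volume-centre position,
and a sub-volume block always equal to the full volume) followed by the
pixel buffer, fastest-varying index first. Supported scalar types: uint8
(the slice exchange format), int16, uint16, float32.

Timestamps are caller-supplied floats, so tests inject fixed clocks and
wire output is reproducible bit-for-bit.

## Transport and the latency harness

The TCP transport and the in-process loopback share one frame-assembly
path, so whole-message delivery, ordering, and 1-byte-chunk reassembly are
tested without sockets. Receives block with a configurable timeout
(default 5 s); a handler error on one message does not tear down the
connection.

Latency is reported in a frame-counting idiom: a round-trip duration is
converted to the number of video frames that would span it at a capture
rate (default 120 Hz), `frames = ceil(ms · rate / 1000)`, and a report
summarises the median, the 80th-percentile frame count and the fraction of
trials within a frame budget (default 6 frames = 50 ms at 120 Hz). The
harness measures in-process perf-counter time around send/receive; this
approximates, but is not equivalent to, camera-observed display latency on
real hardware, so loopback numbers are reported and never asserted against
hardware figures.

## Reslicing

Volumes are 3D scalar grids with positive per-axis spacing, an origin and
an orthonormal direction matrix defining an index→world affine; world is
RAS millimetres throughout. NIfTI loads through nibabel (affines already
RAS); NRRD loads through SimpleITK, whose LPS world is converted by
negating the first two axes. A non-orthonormal direction is warned about
and orthonormalized by SVD.

A plane pose is a rigid transform whose third column is the plane normal,
plus a metric field of view and a pixel grid. Pixel (u, v) samples the
world point `pose · ((u+½)·su − w/2, (v+½)·sv − h/2, 0)` — the rectangle
is centred on the plane origin, pixel centres at half-integer offsets, row
direction along the plane's x axis. Sampling is strictly trilinear
(`scipy.ndimage.map_coordinates`, order 1) with fill value 0 outside the
grid; trilinear interpolation is exact on affine fields, which the tests
exploit as a closed-form oracle.

The output contract fixes only the pixel grid (100 × 100 uint8). The
metric extent and grey mapping are configurable defaults: 100 mm × 100 mm
(1 mm/pixel) and a window spanning the volume's min/max, with bone
(level 400, width 1800 HU) and soft-tissue presets available. The
quantization maps `[level − width/2, level + width/2]` affinely onto
[0, 255], rounding half up. Callers in left-handed frames convert with the
provided single-axis mirror conjugation helper; no auto-detection is done.

## Planning scene

The scene is a pure-data mirror of the planner: a spine model reference, a
CT plane, and an ordered screw list drawn from the fixed catalog of 3
diameters (4.5, 5.0, 6.0 mm) × 7 lengths (30–60 mm in 5 mm steps). A
screw's local frame puts +z along the longitudinal (insertion) axis with
the origin at the head — the catalog never fixes this, so it is a package
convention. `create_screw` appends and activates; the next-screw /
next-diameter / next-length operations cycle their index sets (cycle
lengths 3 and 7 are asserted as catalog bijections). Every pose change
queues exactly one TRANSFORM message — no coalescing — so replaying the
queue into a fresh scene reproduces every pose within float32 wire
precision; a rate limit exists but defaults off. Wire transforms are
restricted to rigid poses; scaled matrices are rejected at validation.

Mesh clipping for the CT-plane cut keeps the half-space the plane normal
points into, splitting crossing triangles at the plane (delegated to
trimesh's plane-slicing routine); an analytic clipped-cube area and an
idempotency check pin the behaviour. Zero-area input triangles are dropped
and counted in the log.

## Pedicle reference geometry

The reference point of a pedicle is the centre of its minimum-diameter
coronal cross-section. Implementation: scan coronal slices (perpendicular
to the anteroposterior axis, axis 1 of an RAS grid, configurable); per
slice take the longest mediolateral and the longest inferosuperior chord
through the binary section; the waist minimises the smaller of the two
chords; the centre crosses the two chord midlines and is lifted to world
millimetres. The mask must be a single connected component.

Two sub-voxel refinements matter at 1 mm spacing. First, when several
rows tie for the longest chord, their midpoints are averaged — for a
symmetric section this recovers the centre to well under a voxel. Second,
integer chord lengths flatten a shallow waist into a plateau of tied
slices; the slice selection therefore anchors on the smallest-area tied
slice and refines the coronal coordinate with a quadratic fit to the
section-area profile over the near-waist window (the area varies smoothly
where chord lengths quantize). The reported section index is the rounded
fit vertex; the centre uses the continuous value. With these refinements
the extracted centre stays within one voxel of the analytic waist across
seeded phantoms, which is the module's acceptance surface. For degenerate
masks (plateau shorter than five slices, e.g. a single voxel) the anchor
slice is used as-is.

## Accuracy metric and grading

The screw's longitudinal axis is intersected with the coronal plane
through the reference centre; the mediolateral and inferosuperior
components of (intersection − centre) are the signed offsets (lateral
positive — the sign flips for left-side pedicles — and superior positive),
and the scalar error is their Euclidean norm. The in-plane reading (rather
than 3D point-to-line distance) is adopted deliberately: it is the
decomposition a two-axis scatter analysis of ML/IS offsets requires. An
axis parallel to the coronal plane is a degeneracy error.

Grading models the screw as a cylinder and samples its lateral surface
(24 circumferential points every 0.5 mm of length) within the pedicle
mask's anteroposterior span. Breach depth is the largest positive value of
a signed distance field (outside-EDT minus inside-EDT of the mask,
trilinearly sampled) minus a half-voxel surface correction — the EDT
measures to voxel centres while the binary surface lies half a voxel
further out. Depths below half a voxel count as contained (grade A): that
is the resolution limit of a binary mask. Grade bins: A no breach,
B < 2 mm, C < 4 mm, D < 6 mm, E ≥ 6 mm; only the A/B success side is
standardised by the grading scale's clinical use, the C/D/E bins follow
the standard published scale. A screw that never enters the AP span is
graded E and flagged. An analytic cylinder-in-cylinder oracle (offset =
R_pedicle − R_screw + protrusion) validates 0/1/6 mm protrusions as A/B/E
at 0.5 mm and 1 mm voxels, and grading is monotone in lateral offset.

## Comparison statistics

Mann–Whitney U uses midranks for ties; U is reported for the first sample.
For pooled sizes ≤ 12 the two-sided p comes from exact enumeration of all
C(n+m, n) group assignments (counting arrangements at least as extreme in
|U − nm/2|); otherwise from the normal approximation with tie-corrected
variance and a 0.5 continuity correction. The implementation is written
in-house because the exact-with-ties branch is part of the contract;
scipy's exact method serves as an independent cross-check in tie-free
tests, and a rank-free brute-force enumerator as the oracle under ties.
Kruskal–Wallis delegates to scipy's tie-corrected H with a chi-square
reference (k − 1 df); all-identical data degenerates to H = 0, p = 1 with
a warning rather than an error.

Non-inferiority of a test success proportion against a reference uses a
one-sided 95 % lower Wald bound on `(p_test − p_ref − δ)` with z = 1.645
and margin δ = −0.10. When either observed proportion is 0 or 1 its
variance term is computed from the add-2 adjusted proportion
`(s + 1)/(n + 2)` so the bound never degenerates to a zero-variance
certainty. The interval method behind a published 0.015 lower limit for
the same comparison is not identifiable from printed counts alone, so
that specific number is reported by the acceptance script (our Wald bound
gives 0.032 for 47/48 vs 48/48) but not asserted. Success percentages are
rounded half away from zero to integers.

## Phantom and study simulator

The phantom is an oracle, not an anatomy model. Each vertebra is a set of
implicit solids voxelized on a 1 mm grid (configurable): an elliptic-
cylinder body (semi-axes 22 × 16 mm, height 30 mm), two pedicles running
posteroanteriorly over 16 mm with elliptic cross-sections whose semi-axes
follow a parabolic waist (full waist width 12.3 mm, height 17.1 mm by
default — lumbar population means; per-spec sampling draws width from
N(12.3, 0.8²) and height from N(17.1, 1.0²) mm), flaring by ×1.3 at both
ends, with a 10° medial convergence implemented as a shear so coronal
sections stay exact ellipses; and an elliptic canal column between the
pedicles. Tissue values are fixed: bone 700 HU, canal 50 HU, background
−1000 HU. Labels partition the foreground (pedicles take precedence at
boundaries). The ground truth carries each pedicle's analytic axis, waist
centre and waist dimensions. A spec whose waist would span fewer than 3
voxels is rejected as unresolvable. Spines stack vertebrae caudal-to-
cranial with a 5 mm gap; level i's labels are offset by 10·i.

What the phantom does not emulate: cortical/trabecular texture, realistic
posterior elements, vertebral endplates, image noise, or the appearance of
clinical CT. Consequently, passing tests demonstrate geometric and
statistical correctness of the pipeline, not segmentation robustness on
real scans.

The error model perturbs the analytic pedicle axis by Gaussian ML/IS
offsets at the waist plus a small direction jitter about the head point.
Per-method defaults are the study conditions: isotropic σ chosen so the
Rayleigh mean σ·√(π/2) matches the observed per-method mean errors
(σ = 1.675 mm for the AR-style arm, 1.037 mm for the desktop-style arm),
a +0.5 mm superior bias reflecting the commonly observed superior
placement preference, and 1° axis jitter. The simulated study is the full
crossed design — 6 users × 2 spines × 8 screws (two per vertebra, L4–L1) =
96 plans, one spine per method per user with the pairing shuffled per
user — and every screw is measured and graded through the same mask-based
code path a real study would use. A single root seed fans out through
`SeedSequence.spawn` to spine-geometry and per-user planning streams, so
any stage is independently reproducible.

Problem sizes throughout (20 phantom specs for parameter recovery, 10,000
draws for the Rayleigh check, 30 latency trials, 1,000 corruption trials)
are chosen to give stable statistics in seconds on one CPU.

## Known limitations

- Only TRANSFORM and IMAGE message types; no STATUS/POLYDATA/VIDEO,
  compression, or TLS. Cross-implementation conformance against a native
  OpenIGTLink stack is not exercised here; the wire layout is instead
  pinned by a second independent decoder and frozen hex dumps.
- Out-of-volume reslice samples fill with 0, which maps to the window
  floor rather than air HU; choose windows accordingly.
- The breach metric's half-voxel containment tolerance means sub-half-voxel
  cortical breaches are indistinguishable from containment at a given mask
  resolution.
- The waist-fit refinement assumes a tube-like mask with a single interior
  minimum; blob-like masks fall back to the anchor slice.
- Latency figures are in-process only and say nothing about rendering or
  network stacks on real devices.
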