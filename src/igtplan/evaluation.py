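"""Placement-accuracy evaluation: pedicle reference geometry, per-screw
accuracy, Gertzbein-Robbins grading, and study-level comparison statistics.

The reference point for each pedicle is the centre of its minimum-diameter
coronal cross-section: scanning coronal slices, the slice whose smaller of
the longest mediolateral and inferosuperior chords is minimal is the waist;
the centre is the intersection of those two chords' midlines.  A screw's
accuracy is the in-plane (ML, IS) offset of its longitudinal axis from that
centre, evaluated in the waist's coronal plane.  Grading follows the
Gertzbein-Robbins scale by maximum cortical breach depth of the screw
cylinder within the pedicle's anteroposterior span: A = no breach, B < 2 mm,
C < 4 mm, D < 6 mm, E >= 6 mm; A and B count as successful.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .reslice import VolumeGrid
from .scene import ScrewPlan
from .stats import (
    NoninferiorityResult,
    RankTestResult,
    kruskal_wallis,
    mann_whitney_u,
    noninferiority_lower_bound,
)

GRADES = ("A", "B", "C", "D", "E")
SUCCESS_GRADES = frozenset({"A", "B"})
# breach-depth upper edges (mm) for grades A..D; E is everything above
_GRADE_EDGES = (0.0, 2.0, 4.0, 6.0)


@dataclass
class PedicleGeometry:
    """Waist cross-section reference geometry of one pedicle."""

    side: str  # "left" | "right"
    level: str  # e.g. "L1".."L4"
    min_section_index: int
    center_point: np.ndarray  # world mm
    width_mm: float  # longest ML chord at the waist
    height_mm: float  # longest IS chord at the waist
    mask: VolumeGrid | None = None
    coronal_axis: int = 1


@dataclass(frozen=True)
class AccuracyResult:
    """Signed in-plane offsets of the screw axis from the pedicle centre."""

    ml_offset_mm: float  # mediolateral, lateral positive
    is_offset_mm: float  # inferosuperior, superior positive
    error_mm: float


@dataclass(frozen=True)
class GradeResult:
    grade: str
    breach_depth_mm: float
    success: bool
    missed_pedicle: bool = False


def _axis_chords(section: np.ndarray) -> tuple[int, float]:
    """Longest chord along axis 0 of a 2D boolean section (in voxels).

    Returns (length, midpoint).  When several rows tie for the longest
    chord their midpoints are averaged, which recovers the centre of a
    symmetric section to sub-voxel precision.
    """
    best_len = 0
    midpoints: list[float] = []
    for k in range(section.shape[1]):
        (idx,) = np.nonzero(section[:, k])
        if not idx.size:
            continue
        length = int(idx[-1] - idx[0] + 1)
        if length > best_len:
            best_len, midpoints = length, [(idx[0] + idx[-1]) / 2.0]
        elif length == best_len:
            midpoints.append((idx[0] + idx[-1]) / 2.0)
    return best_len, float(np.mean(midpoints)) if midpoints else 0.0


def _chords(section: np.ndarray) -> tuple[int, float, int, float]:
    """Longest chords along both axes: (ml_len, ml_mid, is_len, is_mid)."""
    ml_len, ml_mid = _axis_chords(section)
    is_len, is_mid = _axis_chords(section.T)
    return ml_len, ml_mid, is_len, is_mid


def extract_pedicle_geometry(
    mask: VolumeGrid,
    side: str = "",
    level: str = "",
    coronal_axis: int = 1,
) -> PedicleGeometry:
    """Locate the minimum-diameter coronal section and its centre point.

    ``mask`` is a binary VolumeGrid; coronal slices are taken perpendicular
    to ``coronal_axis`` (the anteroposterior axis, 1 for RAS grids).  Per
    slice the longest mediolateral and inferosuperior chords are measured;
    the waist minimises the smaller of the two (ties resolve to the median
    tied slice), and the centre is the crossing of the two chord midlines
    lifted to world millimetres.
    """
    data = np.asarray(mask.scalars) > 0
    if not data.any():
        raise GeometryError("empty pedicle mask (0 components)")
    _, n_components = ndimage.label(data)
    if n_components != 1:
        raise GeometryError(f"pedicle mask must be connected, found {n_components} components")

    axes = [a for a in range(3) if a != coronal_axis]  # (ml axis, is axis)
    moved = np.moveaxis(data, coronal_axis, 0)  # (coronal, ml, is)

    spacing = mask.spacing
    per_slice: dict[int, tuple[int, int, int, float, int, float]] = {}
    for j in range(moved.shape[0]):
        section = moved[j]
        if not section.any():
            continue
        ml_len, ml_mid, is_len, is_mid = _chords(section)
        per_slice[j] = (min(ml_len, is_len), int(section.sum()), ml_len, ml_mid, is_len, is_mid)
    min_key = min(entry[0] for entry in per_slice.values())

    # voxel quantization flattens the waist into a plateau of slices whose
    # chords tie; anchor on the smallest-area tied slice (then the plateau
    # median), and refine the coronal position with a quadratic fit to the
    # smoothly varying section area over the near-waist window
    tied = [j for j, e in per_slice.items() if e[0] == min_key]
    min_area = min(per_slice[j][1] for j in tied)
    tied_area = [j for j in tied if per_slice[j][1] == min_area]
    anchor = tied_area[(len(tied_area) - 1) // 2]
    window = {anchor}
    for step in (-1, 1):
        j = anchor
        while j + step in per_slice and per_slice[j + step][0] <= min_key + 1:
            j += step
            window.add(j)
    js = np.array(sorted(window), dtype=float)
    j_refined = float(anchor)
    if len(js) >= 5:
        coeffs = np.polyfit(js, [per_slice[int(j)][1] for j in js], 2)
        if coeffs[0] > 0:
            j_refined = float(np.clip(-coeffs[1] / (2 * coeffs[0]), js.min(), js.max()))
    j_slice = int(round(j_refined))
    _, _, ml_len, ml_mid, is_len, is_mid = per_slice[j_slice]

    index = np.empty(3, dtype=float)
    index[coronal_axis] = j_refined
    index[axes[0]] = ml_mid
    index[axes[1]] = is_mid
    center_world = mask.index_to_world(index)[0]

    return PedicleGeometry(
        side=side,
        level=level,
        min_section_index=j_slice,
        center_point=center_world,
        width_mm=float(ml_len * spacing[axes[0]]),
        height_mm=float(is_len * spacing[axes[1]]),
        mask=mask,
        coronal_axis=coronal_axis,
    )


def accuracy_error(screw: ScrewPlan, pedicle: PedicleGeometry) -> AccuracyResult:
    """Offset of the screw's longitudinal axis from the pedicle centre.

    The axis is intersected with the coronal plane through the centre point;
    the mediolateral and inferosuperior components of (intersection - centre)
    are returned, with lateral positive (sign flipped for left pedicles) and
    superior positive.
    """
    ap = pedicle.coronal_axis
    axes = [a for a in range(3) if a != ap]
    direction = screw.axis_direction
    if abs(direction[ap]) < 1e-9:
        raise GeometryError("screw axis is parallel to the coronal plane")
    t = (pedicle.center_point[ap] - screw.head_point[ap]) / direction[ap]
    intersection = screw.head_point + t * direction
    offset = intersection - pedicle.center_point
    lateral_sign = -1.0 if pedicle.side == "left" else 1.0
    ml = lateral_sign * float(offset[axes[0]])
    is_ = float(offset[axes[1]])
    return AccuracyResult(ml, is_, float(np.hypot(ml, is_)))


def _grade_from_breach(breach: float) -> str:
    for grade, edge in zip(GRADES, _GRADE_EDGES):
        if breach <= edge if edge == 0.0 else breach < edge:
            return grade
    return "E"


def grade_gertzbein_robbins(
    screw: ScrewPlan,
    pedicle_mask: VolumeGrid,
    coronal_axis: int = 1,
    n_circumference: int = 24,
    axial_step_mm: float = 0.5,
    contained_tol_mm: float | None = None,
) -> GradeResult:
    """Grade a screw by maximum cortical breach depth of its cylinder surface.

    Surface points of the screw cylinder falling inside the pedicle's
    anteroposterior span are evaluated against a signed distance field of
    the mask (outside-EDT minus inside-EDT, zero near the true surface);
    the breach depth is the largest positive signed distance in mm.  Depths
    below ``contained_tol_mm`` (default: half the largest voxel edge, the
    resolution limit of a binary mask) count as contained.  Screws that
    never enter the AP span are graded E and flagged.
    """
    data = np.asarray(pedicle_mask.scalars) > 0
    if not data.any():
        raise GeometryError("empty pedicle mask")
    coords = np.argwhere(data)
    world = pedicle_mask.index_to_world(coords)
    half_voxel = pedicle_mask.spacing[coronal_axis] / 2.0
    ap_lo = world[:, coronal_axis].min() - half_voxel
    ap_hi = world[:, coronal_axis].max() + half_voxel

    direction = screw.axis_direction
    stations = np.arange(0.0, screw.length + 1e-9, axial_step_mm)
    centers = screw.head_point[None, :] + stations[:, None] * direction[None, :]
    inside_span = (centers[:, coronal_axis] >= ap_lo) & (centers[:, coronal_axis] <= ap_hi)
    if not inside_span.any():
        return GradeResult("E", float("inf"), False, missed_pedicle=True)
    centers = centers[inside_span]

    # orthonormal frame perpendicular to the axis
    u = screw.pose.rotation[:, 0]
    v = screw.pose.rotation[:, 1]
    theta = np.linspace(0.0, 2.0 * np.pi, n_circumference, endpoint=False)
    ring = (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)) * (screw.diameter / 2.0)
    points = (centers[:, None, :] + ring[None, :, :]).reshape(-1, 3)

    half_voxel_mm = 0.5 * float(np.max(pedicle_mask.spacing))
    if contained_tol_mm is None:
        contained_tol_mm = half_voxel_mm
    idx = pedicle_mask.world_to_index(points)
    sdf = ndimage.distance_transform_edt(
        ~data, sampling=pedicle_mask.spacing
    ) - ndimage.distance_transform_edt(data, sampling=pedicle_mask.spacing)
    depths = ndimage.map_coordinates(sdf, idx.T, order=1, mode="nearest")
    # the EDT measures to voxel centres; the binary surface lies half a
    # voxel further out, so outside distances carry a half-voxel excess
    breach = float(max(0.0, depths.max(initial=0.0) - half_voxel_mm))
    if breach <= contained_tol_mm:
        return GradeResult("A", 0.0, True)
    grade = _grade_from_breach(breach)
    return GradeResult(grade, breach, grade in SUCCESS_GRADES)


# ---------------------------------------------------------------------------
# study bookkeeping


@dataclass
class StudyRecord:
    """One graded screw plan."""

    user: str
    method: str
    patient: str
    level: str
    side: str
    diameter: float
    length: float
    ml_offset_mm: float
    is_offset_mm: float
    error_mm: float
    grade: str
    pose_matrix: list[float] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.grade in SUCCESS_GRADES

    @property
    def pedicle(self) -> str:
        return f"{self.level}-{self.side}"


def round_half_away(value: float) -> int:
    return int(np.floor(value + 0.5)) if value >= 0 else -int(np.floor(-value + 0.5))


def success_percent(grade_counts: Sequence[int]) -> int:
    """Success percentage (grades A+B), rounded to the nearest integer."""
    counts = list(grade_counts)
    total = sum(counts)
    if total == 0:
        raise ValueError("no graded screws")
    return round_half_away(100.0 * (counts[0] + counts[1]) / total)


@dataclass
class MethodSummary:
    method: str
    n: int
    mean_mm: float
    sd_mm: float
    median_mm: float
    iqr_mm: float
    grade_counts: dict[str, int]
    success_percent: int
    within_3mm_percent: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "median_mm": self.median_mm,
            "iqr_mm": self.iqr_mm,
            "grade_counts": self.grade_counts,
            "success_percent": self.success_percent,
            "within_3mm_percent": self.within_3mm_percent,
        }


@dataclass
class StudySummary:
    methods: dict[str, MethodSummary]
    mann_whitney: RankTestResult | None
    kruskal_by_pedicle: RankTestResult | None
    kruskal_by_user: RankTestResult | None
    noninferiority: NoninferiorityResult | None
    margin: float

    def to_dict(self) -> dict:
        out: dict = {
            "methods": {k: v.to_dict() for k, v in self.methods.items()},
            "margin": self.margin,
        }
        if self.mann_whitney:
            out["mann_whitney"] = {
                "U": self.mann_whitney.statistic,
                "p": self.mann_whitney.p_value,
                "method": self.mann_whitney.method,
            }
        for name, test in (
            ("kruskal_by_pedicle", self.kruskal_by_pedicle),
            ("kruskal_by_user", self.kruskal_by_user),
        ):
            if test:
                out[name] = {"H": test.statistic, "p": test.p_value}
        if self.noninferiority:
            out["noninferiority"] = {
                "lower_bound": self.noninferiority.lower_bound,
                "non_inferior": self.noninferiority.non_inferior,
                "p_test": self.noninferiority.p_test,
                "p_ref": self.noninferiority.p_ref,
                "margin": self.noninferiority.margin,
            }
        return out

    def format_table(self) -> str:
        """Plain-text placement-error and grading tables."""
        lines = ["Method     Mean±SD (mm)   Median/IQR (mm)"]
        for name, s in self.methods.items():
            lines.append(
                f"{name:<10} {s.mean_mm:.1f} ± {s.sd_mm:.1f}      {s.median_mm:.1f}/{s.iqr_mm:.1f}"
            )
        lines.append("")
        lines.append("Method     " + "  ".join(f"{g:>3}" for g in GRADES) + "  % Success")
        for name, s in self.methods.items():
            counts = "  ".join(f"{s.grade_counts[g]:>3}" for g in GRADES)
            lines.append(f"{name:<10} {counts}  {s.success_percent:>8}")
        return "\n".join(lines)


def summarize_study(
    records: Sequence[StudyRecord],
    margin: float = -0.10,
    test_method: str | None = None,
    reference_method: str | None = None,
) -> StudySummary:
    """Aggregate graded records into per-method stats and comparison tests.

    With exactly two methods the error distributions are compared by
    Mann-Whitney U, outcome homogeneity across pedicles and users by
    Kruskal-Wallis, and the success proportions by the non-inferiority
    bound at ``margin``.
    """
    if not records:
        raise ValueError("no records to summarize")
    by_method: dict[str, list[StudyRecord]] = {}
    for rec in records:
        by_method.setdefault(rec.method, []).append(rec)

    methods: dict[str, MethodSummary] = {}
    for name, recs in by_method.items():
        errors = np.array([r.error_mm for r in recs])
        counts = {g: sum(1 for r in recs if r.grade == g) for g in GRADES}
        q75, q25 = np.percentile(errors, [75, 25])
        methods[name] = MethodSummary(
            method=name,
            n=len(recs),
            mean_mm=float(errors.mean()),
            sd_mm=float(errors.std(ddof=1)) if len(recs) > 1 else 0.0,
            median_mm=float(np.median(errors)),
            iqr_mm=float(q75 - q25),
            grade_counts=counts,
            success_percent=success_percent([counts[g] for g in GRADES]),
            within_3mm_percent=float(100.0 * np.mean(errors <= 3.0)),
        )

    mw = kw_ped = kw_user = ni = None
    names = list(by_method)
    if len(names) == 2:
        if test_method is None or reference_method is None:
            # convention: the AR-style method is the test arm if labelled so
            if "AR" in names:
                test_method = "AR"
                reference_method = next(n for n in names if n != "AR")
            else:
                test_method, reference_method = names
        errs_t = [r.error_mm for r in by_method[test_method]]
        errs_r = [r.error_mm for r in by_method[reference_method]]
        mw = mann_whitney_u(errs_t, errs_r)
        s_t = sum(1 for r in by_method[test_method] if r.success)
        s_r = sum(1 for r in by_method[reference_method] if r.success)
        ni = noninferiority_lower_bound(s_t, len(errs_t), s_r, len(errs_r), margin)

    by_pedicle: dict[str, list[float]] = {}
    by_user: dict[str, list[float]] = {}
    for rec in records:
        by_pedicle.setdefault(rec.pedicle, []).append(rec.error_mm)
        by_user.setdefault(rec.user, []).append(rec.error_mm)
    if len(by_pedicle) >= 2:
        kw_ped = kruskal_wallis(list(by_pedicle.values()))
    if len(by_user) >= 2:
        kw_user = kruskal_wallis(list(by_user.values()))

    return StudySummary(
        methods=methods,
        mann_whitney=mw,
        kruskal_by_pedicle=kw_ped,
        kruskal_by_user=kw_user,
        noninferiority=ni,
        margin=margin,
    )


# ---------------------------------------------------------------------------
# CSV / JSON round-trips

_CSV_FIELDS = [
    "user", "method", "patient", "level", "side", "diameter", "length",
    "ml_offset_mm", "is_offset_mm", "error_mm", "grade", "pose_matrix",
]


def write_records_csv(records: Iterable[StudyRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in records:
            row = {k: getattr(rec, k) for k in _CSV_FIELDS}
            row["pose_matrix"] = json.dumps(rec.pose_matrix)
            writer.writerow(row)


def read_records_csv(path: str | Path) -> list[StudyRecord]:
    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            records.append(
                StudyRecord(
                    user=row["user"],
                    method=row["method"],
                    patient=row["patient"],
                    level=row["level"],
                    side=row["side"],
                    diameter=float(row["diameter"]),
                    length=float(row["length"]),
                    ml_offset_mm=float(row["ml_offset_mm"]),
                    is_offset_mm=float(row["is_offset_mm"]),
                    error_mm=float(row["error_mm"]),
                    grade=row["grade"],
                    pose_matrix=json.loads(row["pose_matrix"]) if row["pose_matrix"] else [],
                )
            )
    return records
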