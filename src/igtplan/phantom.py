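"""Procedural lumbar spine phantom with exact analytic ground truth.

The phantom is an oracle, not an anatomy model: each vertebra is a small
set of implicit solids (elliptic-cylinder body, two pedicles with a
parabolic waist and a medial convergence angle, a soft-tissue canal)
voxelized onto a millimetre grid with fixed HU values.  Waist dimensions
default to lumbar pedicle statistics (width 12.3 +/- 0.8 mm, height
17.1 +/- 1.0 mm), so the evaluation pipeline can be validated against
known geometry without any image downloads.

The study simulator reproduces the bookkeeping of a two-method planning
experiment: each of ``n_users`` users instruments ``n_spines`` spines with
``screws_per_spine`` screws, one spine per method, with the spine/method
pairing randomized per user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import GeometryError, ValidationError
from .evaluation import (
    StudyRecord,
    accuracy_error,
    extract_pedicle_geometry,
    grade_gertzbein_robbins,
)
from .messages import RigidTransform
from .reslice import VolumeGrid
from .scene import DEFAULT_CATALOG, ScrewCatalog, ScrewPlan

HU_BONE = 700.0
HU_CANAL = 50.0
HU_BACKGROUND = -1000.0

# label ids within one vertebra
LABEL_BODY = 1
LABEL_LEFT_PEDICLE = 2
LABEL_RIGHT_PEDICLE = 3
LABEL_CANAL = 4
LABELS_PER_LEVEL = 10  # level i uses ids i*10 + local label

LUMBAR_LEVELS = ("L4", "L3", "L2", "L1")  # caudal to cranial stacking order


@dataclass(frozen=True)
class VertebraSpec:
    """Geometry of one phantom vertebra, all dimensions in mm.

    The local frame is RAS-like: x mediolateral (right +), y anteroposterior
    (anterior +), z inferosuperior (superior +), origin at the body centre.
    """

    level: str = "L4"
    body_semi_axes: tuple[float, float] = (22.0, 16.0)  # (ML, AP)
    body_height: float = 30.0
    pedicle_waist_width: float = 12.3  # full ML extent at the waist
    pedicle_waist_height: float = 17.1  # full IS extent at the waist
    pedicle_ap_length: float = 16.0
    pedicle_end_scale: float = 1.3  # flare of the parabolic waist at both ends
    pedicle_offset_x: float = 15.0
    pedicle_anterior_y: float = -12.0  # where the pedicle meets the body
    convergence_deg: float = 10.0
    canal_semi_axes: tuple[float, float] = (6.5, 6.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        if min(self.pedicle_waist_width, self.pedicle_waist_height) < 3.0 * max(self.spacing):
            raise GeometryError(
                "spacing too coarse: the pedicle waist must span at least 3 voxels"
            )
        if self.pedicle_end_scale < 1.0:
            raise ValidationError("waist semi-axes must not exceed end semi-axes")

    @property
    def waist_y(self) -> float:
        return self.pedicle_anterior_y - self.pedicle_ap_length / 2.0

    @classmethod
    def sample(cls, rng: np.random.Generator, level: str = "L4", **overrides) -> "VertebraSpec":
        """Draw waist dimensions from the lumbar population statistics."""
        width = float(rng.normal(12.3, 0.8))
        height = float(rng.normal(17.1, 1.0))
        return cls(
            level=level,
            pedicle_waist_width=width,
            pedicle_waist_height=height,
            **overrides,
        )


@dataclass
class PedicleTruth:
    """Analytic reference for one pedicle."""

    side: str
    level: str
    waist_center: np.ndarray  # world mm
    axis_direction: np.ndarray  # unit vector, anterior-going
    width_mm: float
    height_mm: float
    label: int


@dataclass
class GroundTruth:
    pedicles: list[PedicleTruth]
    label_ids: dict[str, int]

    def pedicle(self, level: str, side: str) -> PedicleTruth:
        for p in self.pedicles:
            if p.level == level and p.side == side:
                return p
        raise KeyError(f"no pedicle {level}/{side}")


def _pedicle_mask_fn(spec: VertebraSpec, side: str, X, Y, Z, z_offset: float):
    sign = 1.0 if side == "right" else -1.0
    x0 = sign * spec.pedicle_offset_x
    y1 = spec.pedicle_anterior_y
    y0 = y1 - spec.pedicle_ap_length
    yw = spec.waist_y
    a_w = spec.pedicle_waist_width / 2.0
    b_w = spec.pedicle_waist_height / 2.0
    half = spec.pedicle_ap_length / 2.0
    flare = 1.0 + (spec.pedicle_end_scale - 1.0) * ((Y - yw) / half) ** 2
    a = a_w * flare
    b = b_w * flare
    tan_th = np.tan(np.deg2rad(spec.convergence_deg))
    xc = x0 - sign * tan_th * (Y - yw)
    inside = (
        (Y >= y0)
        & (Y <= y1)
        & (((X - xc) / a) ** 2 + ((Z - z_offset) / b) ** 2 <= 1.0)
    )
    direction = np.array([-sign * tan_th, 1.0, 0.0])
    direction /= np.linalg.norm(direction)
    truth = PedicleTruth(
        side=side,
        level=spec.level,
        waist_center=np.array([x0, yw, z_offset]),
        axis_direction=direction,
        width_mm=2.0 * a_w,
        height_mm=2.0 * b_w,
        label=LABEL_LEFT_PEDICLE if side == "left" else LABEL_RIGHT_PEDICLE,
    )
    return inside, truth


def _vertebra_extent(spec: VertebraSpec) -> tuple[np.ndarray, np.ndarray]:
    """Local-frame bounding box (lo, hi) covering all structures plus margin."""
    end_a = spec.pedicle_waist_width / 2.0 * spec.pedicle_end_scale
    end_b = spec.pedicle_waist_height / 2.0 * spec.pedicle_end_scale
    tan_th = np.tan(np.deg2rad(spec.convergence_deg))
    x_reach = spec.pedicle_offset_x + end_a + tan_th * spec.pedicle_ap_length / 2.0
    lo = np.array(
        [
            -max(spec.body_semi_axes[0], x_reach) - spec.margin_mm,
            spec.pedicle_anterior_y - spec.pedicle_ap_length - spec.margin_mm,
            -max(spec.body_height / 2.0, end_b) - spec.margin_mm,
        ]
    )
    hi = np.array(
        [
            max(spec.body_semi_axes[0], x_reach) + spec.margin_mm,
            spec.body_semi_axes[1] + spec.margin_mm,
            max(spec.body_height / 2.0, end_b) + spec.margin_mm,
        ]
    )
    return lo, hi


def _voxelize(spec: VertebraSpec, origin: np.ndarray, shape: tuple[int, int, int],
              z_offset: float) -> tuple[np.ndarray, np.ndarray, list[PedicleTruth]]:
    """Rasterize one vertebra into CT (HU) and label arrays on a given grid."""
    spacing = np.asarray(spec.spacing)
    idx = [np.arange(n) for n in shape]
    coords = [origin[d] + spacing[d] * idx[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")

    body = (
        ((X / spec.body_semi_axes[0]) ** 2 + ((Y - 0.0) / spec.body_semi_axes[1]) ** 2 <= 1.0)
        & (np.abs(Z - z_offset) <= spec.body_height / 2.0)
    )
    canal = (
        ((X / spec.canal_semi_axes[0]) ** 2
         + ((Y - (spec.pedicle_anterior_y - spec.pedicle_ap_length / 2.0))
            / spec.canal_semi_axes[1]) ** 2 <= 1.0)
        & (np.abs(Z - z_offset) <= spec.body_height / 2.0)
    )
    left, truth_l = _pedicle_mask_fn(spec, "left", X, Y, Z, z_offset)
    right, truth_r = _pedicle_mask_fn(spec, "right", X, Y, Z, z_offset)

    labels = np.zeros(shape, dtype=np.uint16)
    labels[body] = LABEL_BODY
    labels[canal] = LABEL_CANAL
    labels[left] = LABEL_LEFT_PEDICLE  # pedicles take precedence over body/canal
    labels[right] = LABEL_RIGHT_PEDICLE

    ct = np.full(shape, HU_BACKGROUND, dtype=np.float32)
    ct[(labels == LABEL_BODY) | (labels == LABEL_LEFT_PEDICLE) | (labels == LABEL_RIGHT_PEDICLE)] = HU_BONE
    ct[labels == LABEL_CANAL] = HU_CANAL
    return ct, labels, [truth_l, truth_r]


def make_vertebra(spec: VertebraSpec) -> tuple[VolumeGrid, VolumeGrid, GroundTruth]:
    """Voxelized CT, integer label map and analytic ground truth for one vertebra."""
    lo, hi = _vertebra_extent(spec)
    spacing = np.asarray(spec.spacing)
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing[d])) + 1 for d in range(3))
    origin = lo
    ct, labels, truths = _voxelize(spec, origin, shape, z_offset=0.0)
    ct_grid = VolumeGrid(ct, spacing, origin, np.eye(3))
    label_grid = VolumeGrid(labels, spacing, origin, np.eye(3))
    gt = GroundTruth(
        pedicles=truths,
        label_ids={
            "body": LABEL_BODY,
            "left_pedicle": LABEL_LEFT_PEDICLE,
            "right_pedicle": LABEL_RIGHT_PEDICLE,
            "canal": LABEL_CANAL,
        },
    )
    return ct_grid, label_grid, gt


def make_spine(
    specs: list[VertebraSpec],
    gap_mm: float = 5.0,
) -> tuple[VolumeGrid, VolumeGrid, GroundTruth]:
    """Stack vertebrae caudal-to-cranial along z with inter-body gaps.

    Labels for level index i are offset by i * 10; the ground truth carries
    world-frame waist centres.
    """
    if gap_mm < 0:
        raise GeometryError("overlapping bodies: gap must be non-negative")
    if not specs:
        raise ValidationError("need at least one vertebra spec")
    spacing = np.asarray(specs[0].spacing)
    for spec in specs:
        if not np.allclose(spec.spacing, spacing):
            raise ValidationError("all levels must share one voxel spacing")

    los, his = zip(*(_vertebra_extent(s) for s in specs))
    lo_xy = np.min(np.array(los)[:, :2], axis=0)
    hi_xy = np.max(np.array(his)[:, :2], axis=0)

    heights = [hi[2] - lo[2] for lo, hi in zip(los, his)]
    z_lo = min(lo[2] for lo in los)
    total_height = sum(heights) + gap_mm * (len(specs) - 1)
    lo = np.array([lo_xy[0], lo_xy[1], z_lo])
    hi = np.array([hi_xy[0], hi_xy[1], z_lo + total_height])
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing[d])) + 1 for d in range(3))

    ct = np.full(shape, HU_BACKGROUND, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)
    pedicles: list[PedicleTruth] = []
    label_ids: dict[str, int] = {}

    z_cursor = z_lo
    for i, spec in enumerate(specs):
        spec_lo, spec_hi = _vertebra_extent(spec)
        z_offset = z_cursor - spec_lo[2]  # world z of this vertebra's body centre
        ct_i, labels_i, truths = _voxelize(spec, lo, shape, z_offset=z_offset)
        overwrite = labels_i > 0
        if np.any(labels[overwrite] > 0):
            raise GeometryError(f"level {spec.level} overlaps a previously placed level")
        offset = i * LABELS_PER_LEVEL
        labels[overwrite] = labels_i[overwrite] + offset
        ct[overwrite] = ct_i[overwrite]
        for t in truths:
            t.label += offset
            pedicles.append(t)
        for name, lid in (
            ("body", LABEL_BODY),
            ("left_pedicle", LABEL_LEFT_PEDICLE),
            ("right_pedicle", LABEL_RIGHT_PEDICLE),
            ("canal", LABEL_CANAL),
        ):
            label_ids[f"{spec.level}_{name}"] = lid + offset
        z_cursor += heights[i] + gap_mm

    ct_grid = VolumeGrid(ct, spacing, lo, np.eye(3))
    label_grid = VolumeGrid(labels, spacing, lo, np.eye(3))
    return ct_grid, label_grid, GroundTruth(pedicles=pedicles, label_ids=label_ids)


def default_spine_specs(
    rng: np.random.Generator | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[VertebraSpec]:
    """L4..L1 specs; with a generator, waist sizes vary per level."""
    specs = []
    for level in LUMBAR_LEVELS:
        if rng is None:
            specs.append(VertebraSpec(level=level, spacing=spacing))
        else:
            specs.append(VertebraSpec.sample(rng, level=level, spacing=spacing))
    return specs


def extract_label_mask(labels: VolumeGrid, label_id: int, margin_voxels: int = 8) -> VolumeGrid:
    """Binary mask of one label, cropped to its bounding box plus a margin."""
    data = np.asarray(labels.scalars) == label_id
    if not data.any():
        raise GeometryError(f"label {label_id} not present")
    coords = np.argwhere(data)
    lo = np.maximum(coords.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(coords.max(axis=0) + margin_voxels + 1, data.shape)
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    origin = labels.index_to_world(lo.astype(float))[0]
    return VolumeGrid(sub.astype(np.uint8), labels.spacing, origin, labels.direction)


def bone_surface_mesh(labels: VolumeGrid):
    """Marching-cubes surface of the bone labels as a trimesh mesh."""
    import trimesh
    from skimage import measure

    bone = np.isin(np.asarray(labels.scalars) % LABELS_PER_LEVEL,
                   (LABEL_BODY, LABEL_LEFT_PEDICLE, LABEL_RIGHT_PEDICLE))
    bone = bone & (labels.scalars > 0)
    verts, faces, _normals, _vals = measure.marching_cubes(
        bone.astype(np.uint8), level=0.5, spacing=tuple(labels.spacing)
    )
    verts = verts + labels.origin
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# ---------------------------------------------------------------------------
# plan simulation


@dataclass(frozen=True)
class ErrorModel:
    """Gaussian planning-error model in the waist coronal plane.

    ``sigma_ml``/``sigma_is`` are mediolateral / inferosuperior standard
    deviations (mm), ``mu_is`` a superior-positive bias (mm), and
    ``angle_sd_deg`` an axis-direction jitter about the head point.
    """

    sigma_ml: float = 1.0
    sigma_is: float = 1.0
    mu_is: float = 0.0
    angle_sd_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ml < 0 or self.sigma_is < 0 or self.angle_sd_deg < 0:
            raise ValidationError("error-model spreads must be non-negative")


# default per-method conditions: sigma set so the Rayleigh mean of the
# in-plane error matches the observed per-method means (mean = sigma*sqrt(pi/2)),
# plus a modest superior bias reflecting the common superior placement preference
DEFAULT_ERROR_MODELS = {
    "AR": ErrorModel(sigma_ml=1.675, sigma_is=1.675, mu_is=0.5, angle_sd_deg=1.0),
    "desktop": ErrorModel(sigma_ml=1.037, sigma_is=1.037, mu_is=0.5, angle_sd_deg=1.0),
}


def _jitter_direction(direction: np.ndarray, angle_sd_deg: float,
                      rng: np.random.Generator) -> np.ndarray:
    if angle_sd_deg <= 0:
        return direction
    angle = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    # random rotation axis perpendicular to the screw axis
    seed = rng.normal(size=3)
    axis = np.cross(direction, seed)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return direction
    axis /= norm
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    rotated = (
        direction * cos_a
        + np.cross(axis, direction) * sin_a
        + axis * np.dot(axis, direction) * (1.0 - cos_a)
    )
    return rotated / np.linalg.norm(rotated)


def simulate_plan(
    pedicle: PedicleTruth,
    error_model: ErrorModel,
    rng: np.random.Generator,
    catalog: ScrewCatalog = DEFAULT_CATALOG,
) -> ScrewPlan:
    """A screw plan: the analytic pedicle axis perturbed by the error model.

    The planned axis passes through the waist centre displaced by Gaussian
    ML/IS offsets (lateral positive toward the pedicle's own side), with
    optional direction jitter; dimensions are drawn from the catalog.
    """
    lateral_sign = -1.0 if pedicle.side == "left" else 1.0
    ml = rng.normal(0.0, error_model.sigma_ml)
    is_ = rng.normal(error_model.mu_is, error_model.sigma_is)
    target = pedicle.waist_center + np.array([lateral_sign * ml, 0.0, is_])
    direction = _jitter_direction(pedicle.axis_direction, error_model.angle_sd_deg, rng)
    diameter = float(rng.choice(catalog.diameters))
    length = float(rng.choice(catalog.lengths))
    head = target - direction * (length / 2.0)
    pose = RigidTransform.from_z_axis(direction, head)
    return ScrewPlan(
        id=f"{pedicle.level}-{pedicle.side}",
        pose=pose,
        diameter=diameter,
        length=length,
        level=pedicle.level,
        side=pedicle.side,
    )


def simulate_study(
    n_users: int = 6,
    n_spines: int = 2,
    screws_per_spine: int = 8,
    error_models: dict[str, ErrorModel] | None = None,
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    catalog: ScrewCatalog = DEFAULT_CATALOG,
) -> list[StudyRecord]:
    """Full crossed planning study evaluated through the real pipeline.

    Each user instruments every spine once, one spine per method, with the
    spine/method pairing randomized per user.  Screws are simulated from the
    analytic pedicle axes, then measured and graded against the reference
    geometry extracted from the voxel masks — the same code path a real
    study would use.  Returns one record per screw per method
    (n_users x n_spines x screws_per_spine records in total).
    """
    if error_models is None:
        error_models = DEFAULT_ERROR_MODELS
    if n_spines != len(error_models):
        raise ValidationError("need exactly one method per spine per user")
    if screws_per_spine % 2:
        raise ValidationError("screws_per_spine must pair left/right pedicles")

    root = np.random.SeedSequence(seed)
    spine_seq, plan_seq = root.spawn(2)
    spine_rngs = [np.random.default_rng(s) for s in spine_seq.spawn(n_spines)]

    n_levels = screws_per_spine // 2
    spines = []
    for patient_idx in range(n_spines):
        rng = spine_rngs[patient_idx]
        specs = [
            VertebraSpec.sample(rng, level=level, spacing=spacing)
            for level in LUMBAR_LEVELS[:n_levels]
        ]
        _ct, labels, gt = make_spine(specs)
        references = {}
        for ped in gt.pedicles:
            mask = extract_label_mask(labels, ped.label)
            geometry = extract_pedicle_geometry(mask, side=ped.side, level=ped.level)
            references[(ped.level, ped.side)] = (ped, mask, geometry)
        spines.append((f"Phantom{patient_idx + 1:03d}", references))

    methods = list(error_models)
    records: list[StudyRecord] = []
    user_rngs = [np.random.default_rng(s) for s in plan_seq.spawn(n_users)]
    for user_idx in range(n_users):
        rng = user_rngs[user_idx]
        assignment = list(range(n_spines))
        rng.shuffle(assignment)  # which spine gets which method, per user
        for method_idx, method in enumerate(methods):
            patient, references = spines[assignment[method_idx]]
            model = error_models[method]
            for (level, side), (truth, mask, geometry) in references.items():
                screw = simulate_plan(truth, model, rng, catalog)
                acc = accuracy_error(screw, geometry)
                grade = grade_gertzbein_robbins(screw, mask)
                records.append(
                    StudyRecord(
                        user=f"User{user_idx + 1}",
                        method=method,
                        patient=patient,
                        level=level,
                        side=side,
                        diameter=screw.diameter,
                        length=screw.length,
                        ml_offset_mm=acc.ml_offset_mm,
                        is_offset_mm=acc.is_offset_mm,
                        error_mm=acc.error_mm,
                        grade=grade.grade,
                        pose_matrix=screw.pose.matrix().reshape(16).tolist(),
                    )
                )
    return records
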