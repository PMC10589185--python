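"""Headless planning scene: spine model, CT plane, screw catalog, wire sync.

Mirrors the planner side of the bridge without any rendering: objects hold
rigid poses in world (RAS, mm); every pose change queues one TRANSFORM
message whose metadata names the model to load on the far side, so a remote
scene can be reconstructed exactly from the message stream.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import trimesh

from .errors import ValidationError
from .messages import (
    MessageMetadata,
    RigidTransform,
    decode_transform,
    encode_transform,
)
from .reslice import PlanePose

logger = logging.getLogger(__name__)

# metadata keys carried on every scene TRANSFORM message
KEY_MODEL_FILE = "ModelFileName"
KEY_ROLE = "ObjectRole"  # one of {"spine", "screw", "plane"}
KEY_DIAMETER = "ScrewDiameterMm"
KEY_LENGTH = "ScrewLengthMm"


@dataclass(frozen=True)
class ScrewCatalog:
    """The fixed implant catalog: 3 diameters x 7 lengths (mm)."""

    diameters: tuple[float, ...] = (4.5, 5.0, 6.0)
    lengths: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0)

    def validate(self, diameter: float, length: float) -> None:
        if diameter not in self.diameters:
            raise ValidationError(
                f"diameter {diameter} mm not in catalog {sorted(self.diameters)}"
            )
        if length not in self.lengths:
            raise ValidationError(
                f"length {length} mm not in catalog {sorted(self.lengths)}"
            )

    def __len__(self) -> int:
        return len(self.diameters) * len(self.lengths)


DEFAULT_CATALOG = ScrewCatalog()


@dataclass
class ScrewPlan:
    """One planned pedicle screw.

    The local +z axis is the longitudinal (insertion) axis with the origin at
    the screw head; the pose maps that local frame to world.
    """

    id: str
    pose: RigidTransform
    diameter: float
    length: float
    patient: str = ""
    level: str = ""
    side: str = ""

    @property
    def axis_direction(self) -> np.ndarray:
        return self.pose.rotation[:, 2]

    @property
    def head_point(self) -> np.ndarray:
        return self.pose.translation

    @property
    def tip_point(self) -> np.ndarray:
        return self.pose.translation + self.length * self.axis_direction


def _model_file_for(diameter: float, length: float) -> str:
    return f"screw_d{diameter:g}_l{length:g}.stl"


class PlanningScene:
    """Ordered scene of spine model, CT plane, and screws, synced to the wire."""

    SPINE_ID = "Spine"
    PLANE_ID = "CTPlane"

    def __init__(
        self,
        spine_model_path: str = "spine.stl",
        catalog: ScrewCatalog = DEFAULT_CATALOG,
        clock: Iterable[float] | None = None,
    ) -> None:
        self.catalog = catalog
        self.spine_model_path = spine_model_path
        self.spine_pose = RigidTransform.identity()
        self.ct_plane = PlanePose(RigidTransform.identity())
        self.screws: list[ScrewPlan] = []
        self.active_index: int | None = None
        self._queue: list[bytes] = []
        self._clock = iter(clock) if clock is not None else None
        self._queue_spine()
        self._queue_plane()

    # -- wire sync ---------------------------------------------------------

    def _now(self) -> float:
        if self._clock is not None:
            return next(self._clock)
        return 0.0

    def _queue_message(self, device_name: str, pose: RigidTransform, meta: dict) -> None:
        self._queue.append(
            encode_transform(device_name, pose, self._now(), MessageMetadata(meta))
        )

    def _queue_spine(self) -> None:
        self._queue_message(
            self.SPINE_ID,
            self.spine_pose,
            {KEY_MODEL_FILE: self.spine_model_path, KEY_ROLE: "spine"},
        )

    def _queue_plane(self) -> None:
        self._queue_message(
            self.PLANE_ID, self.ct_plane.pose, {KEY_MODEL_FILE: "", KEY_ROLE: "plane"}
        )

    def _queue_screw(self, screw: ScrewPlan) -> None:
        self._queue_message(
            screw.id,
            screw.pose,
            {
                KEY_MODEL_FILE: _model_file_for(screw.diameter, screw.length),
                KEY_ROLE: "screw",
                KEY_DIAMETER: f"{screw.diameter:g}",
                KEY_LENGTH: f"{screw.length:g}",
            },
        )

    def drain_messages(self) -> list[bytes]:
        """Pop and return every queued TRANSFORM message, oldest first."""
        out, self._queue = self._queue, []
        return out

    # -- screw manipulation ------------------------------------------------

    @property
    def active_screw(self) -> ScrewPlan | None:
        if self.active_index is None:
            return None
        return self.screws[self.active_index]

    def create_screw(
        self,
        diameter: float | None = None,
        length: float | None = None,
        pose: RigidTransform | None = None,
        **target_labels: str,
    ) -> ScrewPlan:
        """Append a new screw (catalog defaults), make it active, queue its message."""
        diameter = self.catalog.diameters[0] if diameter is None else diameter
        length = self.catalog.lengths[0] if length is None else length
        self.catalog.validate(diameter, length)
        screw = ScrewPlan(
            id=f"Screw-{len(self.screws) + 1}",
            pose=pose or RigidTransform.identity(),
            diameter=diameter,
            length=length,
            **target_labels,
        )
        self.screws.append(screw)
        self.active_index = len(self.screws) - 1
        self._queue_screw(screw)
        return screw

    def next_screw(self) -> "PlanningScene":
        """Cycle the active screw; no-op (with a warning) on an empty scene."""
        if not self.screws:
            warnings.warn("next_screw on an empty scene is a no-op")
            return self
        self.active_index = ((self.active_index or 0) + 1) % len(self.screws)
        return self

    def _cycle_dimension(self, attr: str, options: tuple[float, ...]) -> "PlanningScene":
        screw = self.active_screw
        if screw is None:
            warnings.warn(f"next_{attr} with no active screw is a no-op")
            return self
        index = options.index(getattr(screw, attr))
        setattr(screw, attr, options[(index + 1) % len(options)])
        self._queue_screw(screw)
        return self

    def next_diameter(self) -> "PlanningScene":
        return self._cycle_dimension("diameter", self.catalog.diameters)

    def next_length(self) -> "PlanningScene":
        return self._cycle_dimension("length", self.catalog.lengths)

    # -- pose updates ------------------------------------------------------

    def _object_ids(self) -> list[str]:
        return [self.SPINE_ID, self.PLANE_ID] + [s.id for s in self.screws]

    def set_pose(self, object_id: str, transform: RigidTransform) -> None:
        """Replace an object's pose and queue exactly one TRANSFORM message."""
        if not np.all(np.isfinite(transform.matrix())):
            raise ValidationError("pose matrix must be finite")
        if object_id == self.SPINE_ID:
            self.spine_pose = transform
            self._queue_spine()
        elif object_id == self.PLANE_ID:
            self.ct_plane = PlanePose(
                transform, self.ct_plane.field_of_view, self.ct_plane.output_size
            )
            self._queue_plane()
        else:
            for screw in self.screws:
                if screw.id == object_id:
                    screw.pose = transform
                    self._queue_screw(screw)
                    return
            raise KeyError(
                f"unknown object {object_id!r}; known: {self._object_ids()}"
            )

    # -- snapshot ----------------------------------------------------------

    def snapshot(self) -> dict:
        """JSON-serializable scene state (poses as row-major 4x4, mm)."""
        return {
            "spine": {
                "model_file": self.spine_model_path,
                "pose": self.spine_pose.matrix().reshape(16).tolist(),
            },
            "ct_plane": {
                "pose": self.ct_plane.pose.matrix().reshape(16).tolist(),
                "field_of_view_mm": list(self.ct_plane.field_of_view),
                "output_size": list(self.ct_plane.output_size),
            },
            "screws": [
                {
                    "id": s.id,
                    "pose": s.pose.matrix().reshape(16).tolist(),
                    "diameter_mm": s.diameter,
                    "length_mm": s.length,
                    "patient": s.patient,
                    "level": s.level,
                    "side": s.side,
                }
                for s in self.screws
            ],
            "active_index": self.active_index,
        }

    def save_snapshot(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.snapshot(), indent=2))


def reconstruct_scene(messages: Iterable[bytes]) -> PlanningScene:
    """Rebuild a scene by replaying TRANSFORM messages (the remote mirror).

    Uses each message's metadata (object role, model file, screw dimensions)
    to recreate objects, then applies poses in message order.
    """
    scene = PlanningScene.__new__(PlanningScene)
    scene.catalog = DEFAULT_CATALOG
    scene.spine_model_path = "spine.stl"
    scene.spine_pose = RigidTransform.identity()
    scene.ct_plane = PlanePose(RigidTransform.identity())
    scene.screws = []
    scene.active_index = None
    scene._queue = []
    scene._clock = None
    known: dict[str, ScrewPlan] = {}
    for raw in messages:
        device, transform, metadata, _header = decode_transform(raw)
        role = metadata[KEY_ROLE] if KEY_ROLE in metadata else ""
        if role == "spine" or device == PlanningScene.SPINE_ID:
            scene.spine_pose = transform
            if KEY_MODEL_FILE in metadata and metadata[KEY_MODEL_FILE]:
                scene.spine_model_path = metadata[KEY_MODEL_FILE]
        elif role == "plane" or device == PlanningScene.PLANE_ID:
            scene.ct_plane = PlanePose(
                transform, scene.ct_plane.field_of_view, scene.ct_plane.output_size
            )
        else:
            if device not in known:
                screw = ScrewPlan(
                    id=device,
                    pose=transform,
                    diameter=float(metadata[KEY_DIAMETER]),
                    length=float(metadata[KEY_LENGTH]),
                )
                known[device] = screw
                scene.screws.append(screw)
                scene.active_index = len(scene.screws) - 1
            else:
                known[device].pose = transform
                known[device].diameter = float(metadata[KEY_DIAMETER])
                known[device].length = float(metadata[KEY_LENGTH])
    return scene


# ---------------------------------------------------------------------------
# geometry helpers


def screw_mesh(diameter: float, length: float, sections: int = 24) -> trimesh.Trimesh:
    """Display cylinder for a screw, head at the local origin, axis +z."""
    mesh = trimesh.creation.cylinder(radius=diameter / 2.0, height=length, sections=sections)
    mesh.apply_translation([0.0, 0.0, length / 2.0])
    return mesh


def clip_halfspace(mesh: trimesh.Trimesh, plane_pose: RigidTransform) -> trimesh.Trimesh:
    """Clip a triangle mesh by the plane, keeping the side the normal points to.

    Triangles strictly on the negative side are removed; crossing triangles
    are split at the plane, so every output vertex lies on the kept side.
    Degenerate (zero-area) input triangles are dropped first.
    """
    areas = mesh.area_faces
    n_degenerate = int(np.sum(areas <= 1e-12))
    if n_degenerate:
        logger.info("dropping %d degenerate triangles before clipping", n_degenerate)
        mesh = trimesh.Trimesh(
            vertices=mesh.vertices.copy(),
            faces=mesh.faces[areas > 1e-12],
            process=False,
        )
    normal = plane_pose.rotation[:, 2]
    origin = plane_pose.translation
    clipped = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin, cap=False
    )
    if clipped is None:
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    return clipped
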