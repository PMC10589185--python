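"""Oblique CT reslicing: volume grids in RAS mm, plane poses, uint8 slices.

This is the image-server side of the bridge: given a preloaded CT volume and
the pose of a square image plane, interpolate the 100 x 100 uint8 picture at
the plane/volume intersection.  Volumes load from NIfTI (nibabel) or NRRD
(SimpleITK); both are converted to a common RAS-millimetre world frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .messages import BIG_ENDIAN, ImagePayload, RigidTransform

DEFAULT_OUTPUT_SIZE = (100, 100)  # (cols, rows): the fixed slice pixel grid
DEFAULT_FOV_MM = (100.0, 100.0)  # metric extent; 1 mm/pixel at the default size

# window/level presets on the Hounsfield scale
WINDOW_PRESETS = {
    "bone": (400.0, 1800.0),
    "soft": (40.0, 400.0),
}


@dataclass
class VolumeGrid:
    """3D scalar grid with an index -> world (RAS, mm) affine.

    ``scalars`` is indexed [i, j, k]; world = origin + direction @ (spacing * ijk),
    with ijk at voxel centres.
    """

    scalars: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    frame: str = "RAS"

    def __post_init__(self) -> None:
        self.scalars = np.asarray(self.scalars)
        if self.scalars.ndim != 3:
            raise ValidationError("scalars must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-4):
            warnings.warn("non-orthonormal direction matrix; orthonormalizing")
            u, _, vt = np.linalg.svd(self.direction)
            self.direction = u @ vt

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> world affine."""
        m = np.eye(4)
        m[:3, :3] = self.direction * self.spacing
        m[:3, 3] = self.origin
        return m

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        local = (pts - self.origin) @ self.direction  # direction is orthonormal
        return local / self.spacing

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk * self.spacing @ self.direction.T + self.origin


@dataclass
class PlanePose:
    """Pose of the square image plane: local frame -> world, plus pixel grid.

    The plane normal is the third column of the rotation; pixel rows run
    along the local x axis.
    """

    pose: RigidTransform
    field_of_view: tuple[float, float] = DEFAULT_FOV_MM
    output_size: tuple[int, int] = DEFAULT_OUTPUT_SIZE

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.field_of_view):
            raise ValidationError("field_of_view must be positive")
        if any(int(s) <= 0 for s in self.output_size):
            raise GeometryError("output size must be positive")

    @property
    def normal(self) -> np.ndarray:
        return self.pose.rotation[:, 2]

    def pixel_world_points(self) -> np.ndarray:
        """World coordinates of every pixel centre, shape (rows, cols, 3).

        Pixel (u, v) maps to pose . ((u+0.5) su - w/2, (v+0.5) sv - h/2, 0)
        with su = width/cols, sv = height/rows: the rectangle is centred on
        the plane origin and sampled at half-pixel centres.
        """
        cols, rows = self.output_size
        width, height = self.field_of_view
        su, sv = width / cols, height / rows
        u = (np.arange(cols) + 0.5) * su - width / 2.0
        v = (np.arange(rows) + 0.5) * sv - height / 2.0
        uu, vv = np.meshgrid(u, v)  # (rows, cols)
        local = np.stack([uu, vv, np.zeros_like(uu)], axis=-1)
        return self.pose.apply(local)


@dataclass
class Slice2D:
    """Windowed uint8 reslice plus the pose and window that produced it."""

    pixels: np.ndarray
    pose: PlanePose
    window: tuple[float, float]  # (level, width)

    def to_image_payload(self) -> ImagePayload:
        """Wrap as an IMAGE payload whose affine encodes the plane pose.

        The payload origin is the world position of pixel (0, 0); spacing is
        the metric pixel size.
        """
        cols, rows = self.pose.output_size
        width, height = self.pose.field_of_view
        su, sv = width / cols, height / rows
        corner_local = np.array([0.5 * su - width / 2.0, 0.5 * sv - height / 2.0, 0.0])
        origin = self.pose.pose.apply(corner_local)
        pose = RigidTransform(self.pose.pose.rotation, origin)
        # payload array is indexed [i, j, k] = [col, row, slice]
        return ImagePayload.from_array(
            np.ascontiguousarray(self.pixels.T),
            image_to_world=pose,
            spacing=(su, sv, 1.0),
            endianness=BIG_ENDIAN,
        )


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI or NRRD scalar volume into the RAS world frame."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _load_nifti(path)
    if suffixes.endswith((".nrrd", ".nhdr")):
        return _load_nrrd(path)
    raise ValidationError(f"unsupported volume format: {path.name}")


def _from_affine(scalars: np.ndarray, affine: np.ndarray) -> VolumeGrid:
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing == 0):
        raise ValidationError("degenerate affine: zero-length axis")
    direction = linear / spacing
    return VolumeGrid(scalars, spacing, affine[:3, 3], direction)


def _load_nifti(path: Path) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    # nibabel affines are already RAS
    return _from_affine(data, img.affine)


def _load_nrrd(path: Path) -> VolumeGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (k, j, i)
    scalars = np.transpose(data, (2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    # ITK worlds are LPS; negate the first two world axes to get RAS
    flip = np.diag([-1.0, -1.0, 1.0])
    return VolumeGrid(scalars, spacing, flip @ origin, flip @ direction)


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI or NRRD (chosen by extension)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(volume.scalars, volume.affine), str(path))
        return
    if suffixes.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.scalars, (2, 1, 0))))
        flip = np.diag([-1.0, -1.0, 1.0])
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(v) for v in flip @ volume.origin))
        img.SetDirection(tuple((flip @ volume.direction).reshape(9)))
        sitk.WriteImage(img, str(path))
        return
    raise ValidationError(f"unsupported volume format: {path.name}")


def sample_world(volume: VolumeGrid, points_mm: np.ndarray, fill_value: float = 0.0) -> np.ndarray:
    """Trilinear interpolation at world points; outside the grid -> fill value."""
    pts = np.asarray(points_mm, dtype=float)
    single = pts.ndim == 1
    idx = volume.world_to_index(pts.reshape(-1, 3))
    values = ndimage.map_coordinates(
        volume.scalars.astype(float),
        idx.T,
        order=1,
        mode="constant",
        cval=fill_value,
    )
    if single:
        return float(values[0])
    return values.reshape(pts.shape[:-1])


def window_to_uint8(scalars: np.ndarray, level: float, width: float) -> np.ndarray:
    """Affine window/level quantization to uint8, round half up.

    Values at or below level - width/2 map to 0, at or above level + width/2
    to 255, the midpoint to 128.
    """
    if width <= 0:
        raise ValidationError("window width must be positive")
    scaled = (np.asarray(scalars, dtype=float) - (level - width / 2.0)) / width * 255.0
    return np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).clip(0, 255).astype(np.uint8)


def reslice(
    volume: VolumeGrid,
    plane: PlanePose,
    window: tuple[float, float] | str | None = None,
) -> Slice2D:
    """Interpolate the plane/volume intersection and quantize to uint8.

    ``window`` is a (level, width) pair, a preset name ("bone", "soft"), or
    None for the volume's full min/max range.
    """
    if isinstance(window, str):
        try:
            window = WINDOW_PRESETS[window]
        except KeyError:
            raise ValidationError(f"unknown window preset {window!r}") from None
    if window is None:
        lo = float(volume.scalars.min())
        hi = float(volume.scalars.max())
        width = max(hi - lo, 1e-12)
        window = ((lo + hi) / 2.0, width)
    points = plane.pixel_world_points()
    values = sample_world(volume, points)
    pixels = window_to_uint8(values, *window)
    return Slice2D(pixels=pixels, pose=plane, window=tuple(window))


def make_reslice_handler(
    volume: VolumeGrid,
    field_of_view: tuple[float, float] = DEFAULT_FOV_MM,
    output_size: tuple[int, int] = DEFAULT_OUTPUT_SIZE,
    window: tuple[float, float] | str | None = None,
):
    """Message handler answering each plane-pose TRANSFORM with the IMAGE reslice.

    Suitable for both the TCP server and the in-process loopback: it decodes
    the incoming TRANSFORM as the plane pose, reslices the preloaded volume,
    and returns the encoded IMAGE message under the same device name.
    """
    from .messages import decode_transform, encode_image

    def handler(message: bytes) -> bytes:
        device, transform, _metadata, header = decode_transform(message)
        plane = PlanePose(transform, field_of_view, output_size)
        slice2d = reslice(volume, plane, window=window)
        return encode_image(device, slice2d.to_image_payload(), header.timestamp)

    return handler


def flip_handedness(transform: RigidTransform, axis: int = 0) -> RigidTransform:
    """Conjugate a pose by a single-axis mirror (left-handed client frames).

    Converts a pose expressed in a frame whose ``axis`` points the opposite
    way (e.g. a left-handed rendering frame) into the RAS world frame.
    """
    flip = np.eye(3)
    flip[axis, axis] = -1.0
    return RigidTransform(flip @ transform.rotation @ flip, flip @ transform.translation)
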