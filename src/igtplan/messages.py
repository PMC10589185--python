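"""OpenIGTLink message codec: TRANSFORM and IMAGE bodies with metadata.

Implements the fixed 58-byte big-endian message header, the CRC-64/ECMA-182
body checksum, the 48-byte TRANSFORM body (rotation columns then translation,
as 32-bit floats), and the 72-byte IMAGE sub-header followed by the pixel
buffer.  Version-2 headers are emitted by default; attaching key/value
metadata switches the message to the version-3 layout (extended header +
metadata section), and both are accepted on decode.

All multi-byte wire fields are big-endian; pixel buffers honour the
payload's endianness flag.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    FramingError,
    IntegrityError,
    MessageTypeError,
    UnsupportedTypeError,
    ValidationError,
)

HEADER_SIZE = 58
_HEADER_STRUCT = struct.Struct(">H12s20sIIQQ")

# CRC-64/ECMA-182: poly 0x42F0E1EBA9EA3693, init 0, not reflected, no xor-out.
_CRC64_POLY = 0x42F0E1EBA9EA3693
_CRC64_TABLE: list[int] = []
for _b in range(256):
    _r = _b << 56
    for _ in range(8):
        _r = ((_r << 1) ^ _CRC64_POLY if _r & (1 << 63) else _r << 1) & 0xFFFFFFFFFFFFFFFF
    _CRC64_TABLE.append(_r)


def crc64(data: bytes) -> int:
    """CRC-64/ECMA-182 checksum as used by the OpenIGTLink header."""
    crc = 0
    for byte in data:
        crc = ((crc << 8) & 0xFFFFFFFFFFFFFFFF) ^ _CRC64_TABLE[((crc >> 56) ^ byte) & 0xFF]
    return crc


# scalar type codes from the IMAGE message table
SCALAR_CODES = {"uint8": 3, "int16": 4, "uint16": 5, "float32": 10}
_CODE_TO_DTYPE = {3: np.uint8, 4: np.int16, 5: np.uint16, 10: np.float32}

BIG_ENDIAN = 1
LITTLE_ENDIAN = 2


@dataclass(frozen=True)
class MessageHeader:
    """Decoded fixed header of any OpenIGTLink message."""

    protocol_version: int
    type_name: str
    device_name: str
    timestamp: float  # seconds since epoch (32.32 fixed point on the wire)
    body_size: int
    body_crc: int


class RigidTransform:
    """Proper rigid transform: 3x3 rotation (det +1) plus translation in mm."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float).reshape(3)
        if rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.all(np.isfinite(rotation)) or not np.all(np.isfinite(translation)):
            raise ValidationError("transform contains non-finite values")
        if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-6):
            raise ValidationError("rotation columns must be orthonormal (tol 1e-6)")
        if np.linalg.det(rotation) < 0:
            raise ValidationError("rotation must be proper (det +1)")
        self.rotation = rotation
        self.translation = translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_z_axis(cls, direction: np.ndarray, origin: np.ndarray) -> "RigidTransform":
        """Right-handed frame whose local +z points along ``direction``."""
        w = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("axis direction must be non-zero")
        w = w / norm
        seed = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(seed, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return cls(np.column_stack([u, v, w]), origin)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from the local frame to the parent frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def isclose(self, other: "RigidTransform", atol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RigidTransform(t={self.translation.tolist()})"


class MessageMetadata:
    """Ordered, unique-key string metadata attached to a message."""

    def __init__(self, pairs: Iterable[tuple[str, str]] | Mapping[str, str] = ()) -> None:
        if isinstance(pairs, Mapping):
            pairs = list(pairs.items())
        self.pairs: list[tuple[str, str]] = [(str(k), str(v)) for k, v in pairs]
        keys = [k for k, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValidationError("metadata keys must be unique")

    def __bool__(self) -> bool:
        return bool(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, key: str) -> str:
        for k, v in self.pairs:
            if k == key:
                return v
        raise KeyError(key)

    def __contains__(self, key: str) -> bool:
        return any(k == key for k, _ in self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MessageMetadata) and self.pairs == other.pairs

    def __repr__(self) -> str:  # pragma: no cover
        return f"MessageMetadata({self.pairs!r})"


@dataclass
class ImagePayload:
    """Pixel buffer plus the geometry that places it in world (RAS, mm).

    ``image_to_world`` maps image-frame coordinates to world; ``spacing`` is
    per-axis pixel size in mm.  2D slices are encoded as size_ijk = [n, n, 1].
    """

    size_ijk: tuple[int, int, int]
    scalar_type: int  # wire code, see SCALAR_CODES
    num_components: int
    endianness: int  # BIG_ENDIAN or LITTLE_ENDIAN
    image_to_world: RigidTransform
    spacing: tuple[float, float, float]
    buffer: bytes

    def __post_init__(self) -> None:
        if self.scalar_type not in _CODE_TO_DTYPE:
            raise UnsupportedTypeError(
                f"scalar type code {self.scalar_type} not in supported set "
                f"{sorted(_CODE_TO_DTYPE)}"
            )
        if any(int(s) <= 0 for s in self.size_ijk):
            raise ValidationError("size_ijk entries must be positive")
        if self.num_components < 1:
            raise ValidationError("num_components must be >= 1")
        expected = (
            int(np.prod(self.size_ijk))
            * self.num_components
            * np.dtype(_CODE_TO_DTYPE[self.scalar_type]).itemsize
        )
        if len(self.buffer) != expected:
            raise ValidationError(
                f"buffer length {len(self.buffer)} != expected {expected}"
            )

    @property
    def dtype(self) -> np.dtype:
        byteorder = ">" if self.endianness == BIG_ENDIAN else "<"
        return np.dtype(_CODE_TO_DTYPE[self.scalar_type]).newbyteorder(byteorder)

    def to_array(self) -> np.ndarray:
        """Pixel array indexed [i, j, k] (fastest-varying i on the wire)."""
        arr = np.frombuffer(self.buffer, dtype=self.dtype)
        shape = (self.size_ijk[2], self.size_ijk[1], self.size_ijk[0])
        if self.num_components > 1:
            shape = shape + (self.num_components,)
        return np.transpose(arr.reshape(shape), (2, 1, 0) + (() if self.num_components == 1 else (3,)))

    @classmethod
    def from_array(
        cls,
        array: np.ndarray,
        image_to_world: RigidTransform | None = None,
        spacing: Sequence[float] = (1.0, 1.0, 1.0),
        endianness: int = BIG_ENDIAN,
    ) -> "ImagePayload":
        """Build a single-component payload from an [i, j, k] (or 2D) array."""
        arr = np.asarray(array)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValidationError("array must be 2D or 3D")
        name = arr.dtype.name
        if name not in SCALAR_CODES:
            raise UnsupportedTypeError(f"dtype {name} not in supported set {sorted(SCALAR_CODES)}")
        byteorder = ">" if endianness == BIG_ENDIAN else "<"
        wire = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)), dtype=arr.dtype.newbyteorder(byteorder))
        return cls(
            size_ijk=tuple(int(s) for s in arr.shape),
            scalar_type=SCALAR_CODES[name],
            num_components=1,
            endianness=endianness,
            image_to_world=image_to_world or RigidTransform.identity(),
            spacing=tuple(float(s) for s in spacing),
            buffer=wire.tobytes(),
        )


class DecodedTransform(NamedTuple):
    device_name: str
    transform: RigidTransform
    metadata: MessageMetadata
    header: MessageHeader


class DecodedImage(NamedTuple):
    device_name: str
    image: ImagePayload
    metadata: MessageMetadata
    header: MessageHeader


# ---------------------------------------------------------------------------
# header + framing helpers


def _split_timestamp(timestamp: float) -> tuple[int, int]:
    if timestamp < 0:
        raise ValidationError("timestamp must be non-negative")
    sec = int(timestamp)
    frac = int(round((timestamp - sec) * 2**32)) & 0xFFFFFFFF
    return sec & 0xFFFFFFFF, frac


def _encode_ascii(value: str, width: int, what: str) -> bytes:
    raw = value.encode("ascii")
    if len(raw) > width:
        raise ValidationError(f"{what} {value!r} exceeds {width} characters")
    return raw.ljust(width, b"\x00")


def encode_header(
    type_name: str,
    device_name: str,
    body: bytes,
    timestamp: float,
    protocol_version: int,
) -> bytes:
    sec, frac = _split_timestamp(timestamp)
    return _HEADER_STRUCT.pack(
        protocol_version,
        _encode_ascii(type_name, 12, "type_name"),
        _encode_ascii(device_name, 20, "device_name"),
        sec,
        frac,
        len(body),
        crc64(body),
    )


def decode_header(data: bytes) -> MessageHeader:
    if len(data) < HEADER_SIZE:
        raise FramingError(f"header needs {HEADER_SIZE} bytes, got {len(data)}")
    version, tname, dname, sec, frac, body_size, body_crc = _HEADER_STRUCT.unpack(
        data[:HEADER_SIZE]
    )
    return MessageHeader(
        protocol_version=version,
        type_name=tname.rstrip(b"\x00").decode("ascii"),
        device_name=dname.rstrip(b"\x00").decode("ascii"),
        timestamp=sec + frac / 2**32,
        body_size=body_size,
        body_crc=body_crc,
    )


def _checked_body(data: bytes) -> tuple[MessageHeader, bytes]:
    header = decode_header(data)
    body = data[HEADER_SIZE : HEADER_SIZE + header.body_size]
    if len(body) != header.body_size:
        raise FramingError(
            f"truncated body: header promises {header.body_size} bytes, "
            f"got {len(body)}"
        )
    if crc64(body) != header.body_crc:
        raise IntegrityError("body CRC mismatch")
    return header, body


# ---------------------------------------------------------------------------
# version-3 extended header + metadata section

_EXT_HEADER_STRUCT = struct.Struct(">HHII")  # ext size, meta header size, meta size, msg id
_US_ASCII = 3  # IANA MIBenum


def _encode_metadata(metadata: MessageMetadata) -> tuple[bytes, bytes]:
    index = struct.pack(">H", len(metadata.pairs))
    blob = b""
    for key, value in metadata.pairs:
        kraw, vraw = key.encode("utf-8"), value.encode("utf-8")
        index += struct.pack(">HHI", len(kraw), _US_ASCII, len(vraw))
        blob += kraw + vraw
    return index, blob


def _decode_metadata(meta_header: bytes, meta_data: bytes) -> MessageMetadata:
    (count,) = struct.unpack_from(">H", meta_header, 0)
    entries = []
    offset = 2
    for _ in range(count):
        ksize, _encoding, vsize = struct.unpack_from(">HHI", meta_header, offset)
        offset += 8
        entries.append((ksize, vsize))
    pairs = []
    pos = 0
    for ksize, vsize in entries:
        key = meta_data[pos : pos + ksize].decode("utf-8")
        pos += ksize
        value = meta_data[pos : pos + vsize].decode("utf-8")
        pos += vsize
        pairs.append((key, value))
    return MessageMetadata(pairs)


def _wrap_body(content: bytes, metadata: MessageMetadata | None) -> tuple[bytes, int]:
    """Return (body, protocol_version): plain v2 body, or v3 with metadata."""
    if not metadata:
        return content, 2
    meta_header, meta_data = _encode_metadata(metadata)
    ext = _EXT_HEADER_STRUCT.pack(12, len(meta_header), len(meta_data), 0)
    return ext + content + meta_header + meta_data, 3


def _unwrap_body(header: MessageHeader, body: bytes) -> tuple[bytes, MessageMetadata]:
    if header.protocol_version < 3:
        return body, MessageMetadata()
    ext_size, meta_header_size, meta_size, _msg_id = _EXT_HEADER_STRUCT.unpack_from(body, 0)
    if ext_size < 12 or ext_size + meta_header_size + meta_size > len(body):
        raise FramingError("inconsistent extended-header sizes")
    content = body[ext_size : len(body) - meta_header_size - meta_size]
    meta_header = body[len(body) - meta_header_size - meta_size : len(body) - meta_size]
    meta_data = body[len(body) - meta_size :]
    return content, _decode_metadata(meta_header, meta_data)


# ---------------------------------------------------------------------------
# TRANSFORM codec


def encode_transform(
    device_name: str,
    transform: RigidTransform,
    timestamp: float = 0.0,
    metadata: Mapping[str, str] | Sequence[tuple[str, str]] | MessageMetadata | None = None,
) -> bytes:
    """Encode a TRANSFORM message: 12 big-endian float32, columns then translation."""
    meta = metadata if isinstance(metadata, MessageMetadata) else MessageMetadata(metadata or ())
    values = np.concatenate([transform.rotation.T.reshape(9), transform.translation])
    content = struct.pack(">12f", *values)
    body, version = _wrap_body(content, meta)
    return encode_header("TRANSFORM", device_name, body, timestamp, version) + body


def decode_transform(data: bytes) -> DecodedTransform:
    header, body = _checked_body(data)
    if header.type_name != "TRANSFORM":
        raise MessageTypeError(f"expected TRANSFORM, got {header.type_name!r}")
    content, metadata = _unwrap_body(header, body)
    if len(content) != 48:
        raise FramingError(f"TRANSFORM content must be 48 bytes, got {len(content)}")
    values = np.array(struct.unpack(">12f", content), dtype=float)
    rotation = values[:9].reshape(3, 3).T
    try:
        transform = RigidTransform(rotation, values[9:12])
    except ValidationError:
        # float32 wire precision can violate the 1e-6 orthonormality gate;
        # polish only then, so clean messages re-encode byte-identically
        u, _, vt = np.linalg.svd(rotation)
        transform = RigidTransform(u @ vt, values[9:12])
    return DecodedTransform(header.device_name, transform, metadata, header)


# ---------------------------------------------------------------------------
# IMAGE codec

_IMAGE_SUBHEADER = struct.Struct(">HBBBB3H12f3H3H")  # 72 bytes
_RAS_COORD = 1


def encode_image(
    device_name: str,
    image: ImagePayload,
    timestamp: float = 0.0,
    metadata: Mapping[str, str] | Sequence[tuple[str, str]] | MessageMetadata | None = None,
) -> bytes:
    meta = metadata if isinstance(metadata, MessageMetadata) else MessageMetadata(metadata or ())
    size = image.size_ijk
    axes = image.image_to_world.rotation * np.asarray(image.spacing)  # columns scaled
    center_index = (np.asarray(size, dtype=float) - 1.0) / 2.0
    center = image.image_to_world.apply(center_index * np.asarray(image.spacing))
    fields = (
        1,  # IMAGE sub-header version
        image.num_components,
        image.scalar_type,
        image.endianness,
        _RAS_COORD,
        *size,
        *axes[:, 0], *axes[:, 1], *axes[:, 2], *center,
        0, 0, 0,
        *size,
    )
    content = _IMAGE_SUBHEADER.pack(*fields) + image.buffer
    body, version = _wrap_body(content, meta)
    return encode_header("IMAGE", device_name, body, timestamp, version) + body


def decode_image(data: bytes) -> DecodedImage:
    header, body = _checked_body(data)
    if header.type_name != "IMAGE":
        raise MessageTypeError(f"expected IMAGE, got {header.type_name!r}")
    content, metadata = _unwrap_body(header, body)
    if len(content) < _IMAGE_SUBHEADER.size:
        raise FramingError("IMAGE content shorter than its 72-byte sub-header")
    fields = _IMAGE_SUBHEADER.unpack_from(content, 0)
    (_version, num_components, scalar_type, endianness, _coord) = fields[:5]
    size = fields[5:8]
    matrix = np.array(fields[8:20], dtype=float)
    axes = np.column_stack([matrix[0:3], matrix[3:6], matrix[6:9]])
    center = matrix[9:12]
    spacing = np.linalg.norm(axes, axis=0)
    if np.any(spacing == 0):
        raise FramingError("zero-length image axis vector")
    rotation = axes / spacing
    u, _, vt = np.linalg.svd(rotation)
    rotation = u @ vt
    center_index = (np.asarray(size, dtype=float) - 1.0) / 2.0
    origin = center - rotation @ (center_index * spacing)
    if scalar_type not in _CODE_TO_DTYPE:
        raise UnsupportedTypeError(
            f"scalar type code {scalar_type} not in supported set {sorted(_CODE_TO_DTYPE)}"
        )
    image = ImagePayload(
        size_ijk=tuple(int(s) for s in size),
        scalar_type=scalar_type,
        num_components=num_components,
        endianness=endianness,
        image_to_world=RigidTransform(rotation, origin),
        spacing=tuple(float(s) for s in spacing),
        buffer=content[_IMAGE_SUBHEADER.size :],
    )
    return DecodedImage(header.device_name, image, metadata, header)


def decode_any(data: bytes) -> DecodedTransform | DecodedImage:
    """Dispatch on the header's type name."""
    header = decode_header(data)
    if header.type_name == "TRANSFORM":
        return decode_transform(data)
    if header.type_name == "IMAGE":
        return decode_image(data)
    raise MessageTypeError(f"unsupported message type {header.type_name!r}")
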