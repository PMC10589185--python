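"""Wire codec: CRC, round-trips, corruption detection, dual-decoder parity."""

import struct

import numpy as np
import pytest

from igtplan import messages as m
from igtplan.errors import (
    IntegrityError,
    MessageTypeError,
    UnsupportedTypeError,
    ValidationError,
)

from .conftest import random_rigid_transform

POLY = 0x42F0E1EBA9EA3693
MASK = 0xFFFFFFFFFFFFFFFF


def crc64_bitwise(data: bytes) -> int:
    """Independent bit-by-bit long-division oracle for CRC-64/ECMA-182."""
    crc = 0
    for byte in data:
        crc ^= byte << 56
        for _ in range(8):
            crc = ((crc << 1) ^ POLY) & MASK if crc & (1 << 63) else (crc << 1) & MASK
    return crc


class TestCrc64:
    def test_empty_input_is_init_value(self):
        assert m.crc64(b"") == 0

    def test_check_vector(self):
        assert m.crc64(b"123456789") == 0x6C40DF5F0B497347
        assert crc64_bitwise(b"123456789") == 0x6C40DF5F0B497347

    def test_matches_bitwise_oracle_on_random_strings(self, rng):
        for _ in range(50):
            data = rng.integers(0, 256, rng.integers(0, 64)).astype(np.uint8).tobytes()
            assert m.crc64(data) == crc64_bitwise(data)

    def test_deterministic(self):
        data = b"\x00\xffpedicle"
        assert m.crc64(data) == m.crc64(data)


def decode_transform_from_layout_table(raw: bytes):
    """Second, fully independent TRANSFORM decoder written from the wire table.

    Header: >u16 version, 12s type, 20s device, u32 sec, u32 frac, u64 size,
    u64 crc.  Body (version 2): 12 big-endian float32, rotation columns then
    translation.
    """
    version, tname, dname, sec, frac, size, crc = struct.unpack(">H12s20sIIQQ", raw[:58])
    assert tname.rstrip(b"\0") == b"TRANSFORM"
    body = raw[58 : 58 + size]
    values = struct.unpack(">12f", body[:48])
    rotation = np.array(values[:9]).reshape(3, 3).T
    translation = np.array(values[9:12])
    return dname.rstrip(b"\0").decode(), rotation, translation, sec + frac / 2**32, crc


class TestTransformCodec:
    def test_identity_body_floats(self):
        raw = m.encode_transform("dev", m.RigidTransform.identity(), 0.0)
        body = raw[58:]
        assert len(body) == 48
        assert struct.unpack(">12f", body) == (1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0)

    def test_roundtrip_random_transforms(self, rng):
        for _ in range(25):
            t = random_rigid_transform(rng)
            decoded = m.decode_transform(m.encode_transform("Screw-3", t, 12.25))
            assert decoded.device_name == "Screw-3"
            assert decoded.transform.isclose(t, atol=1e-5)

    def test_independent_decoder_agrees(self, rng):
        """Dual-implementation oracle: both decoders read the same bytes."""
        for _ in range(10):
            t = random_rigid_transform(rng)
            raw = m.encode_transform("Plane", t, 7.5)
            dev, rot, trans, ts, crc = decode_transform_from_layout_table(raw)
            ours = m.decode_transform(raw)
            assert dev == ours.device_name
            assert np.allclose(rot, ours.transform.rotation, atol=1e-6)
            assert np.allclose(trans, ours.transform.translation, atol=1e-4)
            assert ts == pytest.approx(ours.header.timestamp, abs=1e-6)
            assert crc == m.crc64(raw[58:])

    def test_device_name_too_long_rejected(self):
        with pytest.raises(ValidationError, match="20 characters"):
            m.encode_transform("x" * 21, m.RigidTransform.identity(), 0.0)

    def test_single_byte_corruption_detected(self, rng):
        raw = bytearray(m.encode_transform("dev", m.RigidTransform.identity(), 1.0))
        pos = int(rng.integers(58, len(raw)))
        raw[pos] ^= 0x40
        with pytest.raises(IntegrityError):
            m.decode_transform(bytes(raw))

    def test_wrong_type_rejected(self):
        img = m.ImagePayload.from_array(np.zeros((1, 1), dtype=np.uint8))
        raw = m.encode_image("dev", img, 0.0)
        with pytest.raises(MessageTypeError):
            m.decode_transform(raw)

    def test_metadata_roundtrip_preserves_order(self):
        meta = [("ModelFileName", "spine.stl"), ("ObjectRole", "spine"), ("Zed", "1")]
        raw = m.encode_transform("Spine", m.RigidTransform.identity(), 0.0, meta)
        decoded = m.decode_transform(raw)
        assert decoded.metadata.pairs == meta
        assert decoded.header.protocol_version == 3

    def test_no_metadata_emits_version_2(self):
        raw = m.encode_transform("Spine", m.RigidTransform.identity(), 0.0)
        assert m.decode_header(raw).protocol_version == 2

    def test_duplicate_metadata_keys_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            m.MessageMetadata([("a", "1"), ("a", "2")])


class TestImageCodec:
    def test_100x100_uint8_roundtrips_exactly(self):
        img = m.ImagePayload.from_array(np.full((100, 100), 7, dtype=np.uint8))
        decoded = m.decode_image(m.encode_image("Reslice", img, 3.0))
        assert decoded.image.size_ijk == (100, 100, 1)
        assert decoded.image.buffer == img.buffer

    def test_single_zero_pixel(self):
        img = m.ImagePayload.from_array(np.zeros((1, 1), dtype=np.uint8))
        decoded = m.decode_image(m.encode_image("d", img, 0.0))
        assert decoded.image.to_array().ravel().tolist() == [0]

    @pytest.mark.parametrize("dtype,endian", [
        (np.uint8, m.BIG_ENDIAN),
        (np.int16, m.BIG_ENDIAN),
        (np.uint16, m.LITTLE_ENDIAN),
        (np.float32, m.LITTLE_ENDIAN),
    ])
    def test_buffer_hash_preserved_all_scalar_types(self, rng, dtype, endian):
        arr = (rng.integers(0, 200, (9, 7, 5))).astype(dtype)
        img = m.ImagePayload.from_array(arr, spacing=(1, 1, 2.5), endianness=endian)
        decoded = m.decode_image(m.encode_image("V", img, 0.0))
        assert hash(decoded.image.buffer) == hash(img.buffer)
        assert np.array_equal(decoded.image.to_array(), arr)
        assert decoded.image.spacing == (1, 1, 2.5)

    def test_pose_roundtrip(self, rng):
        pose = random_rigid_transform(rng)
        img = m.ImagePayload.from_array(
            np.zeros((10, 12), dtype=np.uint8), image_to_world=pose, spacing=(0.5, 0.5, 1.0)
        )
        decoded = m.decode_image(m.encode_image("d", img, 0.0))
        assert decoded.image.image_to_world.isclose(pose, atol=1e-3)

    def test_unsupported_scalar_type_rejected(self):
        with pytest.raises(UnsupportedTypeError):
            m.ImagePayload.from_array(np.zeros((2, 2), dtype=np.float64))

    def test_wire_bytes_identical_across_runs(self):
        img = m.ImagePayload.from_array(np.arange(6, dtype=np.uint8).reshape(2, 3))
        assert m.encode_image("d", img, 1.5) == m.encode_image("d", img, 1.5)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self, rng):
        t = random_rigid_transform(rng)
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation, 0, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            m.RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValidationError):
            m.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestHexFixtures:
    """The documented wire dumps decode to their stated contents."""

    @staticmethod
    def _load(path):
        raw = bytearray()
        for line in path.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            raw.extend(int(tok, 16) for tok in line.split()[1:])
        return bytes(raw)

    def test_transform_dump(self, fixtures_dir):
        raw = self._load(fixtures_dir / "transform_message.hex")
        decoded = m.decode_transform(raw)
        assert decoded.device_name == "CTPlane"
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        expected = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        assert np.allclose(decoded.transform.rotation, expected, atol=1e-6)
        assert np.allclose(decoded.transform.translation, [10, -20, 5], atol=1e-5)
        assert decoded.header.timestamp == pytest.approx(1700000000.5)

    def test_image_dump(self, fixtures_dir):
        raw = self._load(fixtures_dir / "image_message.hex")
        decoded = m.decode_image(raw)
        assert decoded.device_name == "Reslice"
        assert decoded.image.size_ijk == (4, 3, 1)
        assert np.array_equal(
            decoded.image.to_array()[:, :, 0], np.arange(12, dtype=np.uint8).reshape(4, 3)
        )
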