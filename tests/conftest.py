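from pathlib import Path

import numpy as np
import pytest

from igtplan.messages import RigidTransform
from igtplan.reslice import VolumeGrid

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rigid_transform(rng: np.random.Generator) -> RigidTransform:
    """Uniform-ish random proper rotation (QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return RigidTransform(q, rng.uniform(-100, 100, 3))


@pytest.fixture
def fixtures_dir():
    return FIXTURES


@pytest.fixture(scope="session")
def cylinder_pedicle_mask():
    """Circular-cylinder pedicle, radius 6 mm, axis +y, 0.5 mm voxels.

    Centre of the cylinder axis at world (20, *, 20); the analytic geometry
    makes breach depths for laterally offset screws exactly computable.
    """
    sp = 0.5
    n = 80
    xx = (np.arange(n) + 0.5) * sp
    X, Y, Z = np.meshgrid(xx, xx, xx, indexing="ij")
    c = 20.0
    mask = ((X - c) ** 2 + (Z - c) ** 2 <= 6.0**2) & (Y > 10) & (Y < 30)
    return VolumeGrid(mask.astype(np.uint8), (sp, sp, sp), (sp / 2, sp / 2, sp / 2), np.eye(3))
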