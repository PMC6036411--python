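import numpy as np
import pytest

from regqa.transforms import PatientShift, RotationSpec, ShiftedRole


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_shift():
    """Rotation-case phantom shift: 5 mm Lt, 15 mm Ant, 20 mm Sup (stationary shifted)."""
    return PatientShift(((5.0, "Lt"), (15.0, "Ant"), (20.0, "Sup")), ShiftedRole.STATIONARY)


@pytest.fixture
def phantom_rotation():
    """Rotation-case phantom angles: -5 deg about x, 8 about y, 10 about z."""
    return RotationSpec(-5.0, 8.0, 10.0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
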