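import numpy as np
import pytest

from voxmouse.camera import CameraModel, build_virtual_rig


@pytest.fixture(scope="session")
def rig():
    """Default 10-camera virtual rig (4 below + 6 lateral, 1024 px sensors)."""
    return build_virtual_rig()


@pytest.fixture(scope="session")
def small_rig():
    """Coarse rig for fast plumbing tests."""
    return build_virtual_rig(image_size=(384, 384))


@pytest.fixture()
def toy_camera():
    """Axis-aligned unit camera used in closed-form projection examples."""
    return CameraModel(
        id="toy",
        rotation=np.eye(3),
        translation=np.zeros(3),
        focal=np.array([100.0, 100.0]),
        principal_point=np.array([50.0, 50.0]),
        image_size=(101, 101),
    )
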