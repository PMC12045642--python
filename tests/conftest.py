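import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from videba.synthetic import CameraRig, SwimScenario
from videba.types import PointTrack, PoseTrackSet


@pytest.fixture(scope="session")
def rig() -> CameraRig:
    return CameraRig.default()


@pytest.fixture(scope="session")
def scenario() -> SwimScenario:
    return SwimScenario()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pose(u, v, likelihood, camera_id="top", fps=90.0, body_point="eye") -> PoseTrackSet:
    u = np.asarray(u, dtype=float)
    return PoseTrackSet(
        camera_id=camera_id,
        frames=np.arange(len(u)),
        points={body_point: PointTrack(u=u, v=np.asarray(v, float), likelihood=np.asarray(likelihood, float))},
        fps=fps,
    )
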