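import numpy as np
import pytest

from posturekit.skeleton import N_JOINTS, Recording
from posturekit.synthetic import NoiseModel, PostureScript, benchmark_frame_table


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_recording(
    rng: np.random.Generator,
    n_frames: int = 5,
    frame_rate: float = 30.0,
    sentinel_mask=None,
) -> Recording:
    """A small random (anatomy-free) recording for I/O and geometry tests."""
    timestamps = np.arange(n_frames) / frame_rate
    coords = rng.uniform(-2.0, 2.0, (n_frames, N_JOINTS, 3))
    if sentinel_mask is not None:
        sentinel_mask = np.asarray(sentinel_mask, dtype=bool)
        coords[sentinel_mask] = 999.0
    return Recording(
        subject_id="sub",
        subject_height=1.70,
        camera_id="cam0",
        timestamps=timestamps,
        coords=coords,
        frame_rate=frame_rate,
    )


@pytest.fixture(scope="session")
def clean_benchmark():
    """Noise-free two-subject benchmark: one posture cycle, no dropouts."""
    return benchmark_frame_table(
        n_subjects=2,
        script=PostureScript.default(cycles=1),
        noise=NoiseModel.none(),
        seed=1234,
    )


@pytest.fixture(scope="session")
def noisy_benchmark():
    """Three-subject benchmark at the default noise/burst levels."""
    return benchmark_frame_table(
        n_subjects=3,
        script=PostureScript.default(cycles=2),
        noise=NoiseModel(),
        seed=4321,
    )
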