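import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def adl_session():
    """One 20 s ADL session simulated without noise or mounting offsets."""
    from sparsetrack import pipeline as P
    from sparsetrack.synthkin import SimConfig, generate_adl_motion, simulate_imu_stream

    script = generate_adl_motion(20.0, seed=7)
    stream, gt = simulate_imu_stream(script, config=SimConfig(seed=7))
    return P.Session(stream, gt, "adl")


@pytest.fixture(scope="session")
def isolation_session():
    """One 10 s locked-humerus elbow-flexion hard negative at 1 Hz."""
    from sparsetrack import pipeline as P
    from sparsetrack.synthkin import SimConfig, generate_isolation_task, simulate_imu_stream

    script = generate_isolation_task("elbow_flexion", 1.0, seed=9)
    stream, gt = simulate_imu_stream(script, config=SimConfig(seed=9))
    return P.Session(stream, gt, script.label)


@pytest.fixture(scope="session")
def tiny_results():
    """A briefly fitted reduced model on a miniature dataset, for
    inference-path tests that need a real SparseTrackResults object."""
    from sparsetrack import pipeline as P
    from sparsetrack.model import ModelConfig

    sessions = P.simulate_sessions(5, 2, 16.0, seed=3)
    ds = P.MotionDataset.from_sessions(sessions, L=120, stride=60, seed=3)
    mc = ModelConfig.reduced(L=120, d_model=32, n_heads=4, d_ff=64, n_layers=1)
    rc = P.RunConfig(epochs=1, seed=3, batch_size=16)
    return P.SparseTrackModel(ds, model_config=mc, run_config=rc).fit()
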