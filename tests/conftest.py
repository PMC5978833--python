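import numpy as np
import pytest

from reachmap import (
    AnalysisConfig,
    MotionScenario,
    QuaternionSample,
    analyze_stream,
    default_emg_surrogate,
    simulate_trial,
)

IDENTITY_REFERENCE = (1.0, 0.0, 0.0, 0.0)


def quat_multiply(q1, q2):
    """Hamilton product of (w, x, y, z) quaternions — independent oracle."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def sandwich_rotate(q, v):
    """Rotate vector v by quaternion q via q * (0, v) * q^-1."""
    q = np.asarray(q, dtype=float)
    q_conj = q * np.array([1.0, -1.0, -1.0, -1.0])
    return quat_multiply(quat_multiply(q, np.concatenate([[0.0], v])), q_conj)[1:]


def random_unit_quaternions(n, rng):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def healthy_trial():
    """One noise-free protocol trial with EMG, analyzed at defaults."""
    scenario = MotionScenario(seed=7, duration=30.0)
    df, truth = simulate_trial(scenario, default_emg_surrogate(noise_sd=0.0))
    analysis = analyze_stream(df, AnalysisConfig(reference=IDENTITY_REFERENCE))
    return df, truth, analysis


def make_sample(qw, qx, qy, qz, t=0.0):
    return QuaternionSample.create(t, qw, qx, qy, qz)
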