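"""Synthetic motion and EMG generator standing in for the hardware.

Two scenarios are emulated:

* the clinical protocol — four consecutive expanding circuits of arm
  elevation sweeping the azimuth range, the outermost circuit tracing
  the subject's maximal envelope ``B(alpha)``;
* the gimbal bench rig — a two-servo test stand driving known pitch
  (elevation) and yaw (azimuth) schedules, used to validate orientation
  accuracy against ground truth.

Orientation noise is injected in angle space: independent Gaussian
perturbations of the commanded azimuth and elevation (wrapped/clipped to
their ranges) before quaternion synthesis, so the stated sd is directly
the angular read-out error — and EMG channels as a per-channel activation
surface ``a(alpha, beta)`` in [0, 1] scaled to 100 with multiplicative
Gaussian noise, clipped at zero.  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ReachmapError

EnvelopeFunction = Callable[[np.ndarray], np.ndarray]


def healthy_envelope(alpha) -> np.ndarray:
    """Default healthy-shoulder envelope ``B(alpha)`` in degrees.

    A smooth two-harmonic profile anchored at roughly 150 deg of flexion
    (azimuth 0), 140 deg of abduction (azimuth +90), 80 deg medially and
    60 deg posteriorly — the shape of a healthy maximal workspace, not a
    reproduction of any subject's data.
    """
    a = np.radians(np.asarray(alpha, dtype=float))
    return 107.5 + 45.0 * np.cos(a) + 30.0 * np.sin(a) - 2.5 * np.cos(2 * a)


def frozen_envelope(alpha) -> np.ndarray:
    """Frozen-shoulder envelope: scaled down and capped at 70 deg."""
    return np.minimum(0.55 * healthy_envelope(alpha), 70.0)


@dataclass
class MotionScenario:
    """Protocol-compliant circuit scenario.

    ``circuit_fractions`` are the fractions of the maximal envelope
    traced by each consecutive circuit (strictly increasing, last = 1;
    four circuits by protocol).  ``azimuth_range`` restricts the swept
    azimuth arc (a frozen shoulder cannot reach posteriorly).
    ``orientation_noise_sd`` is the angular jitter in degrees.
    """

    envelope_function: EnvelopeFunction = healthy_envelope
    circuit_fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0)
    sample_rate: float = 100.0
    duration: float = 60.0
    orientation_noise_sd: float = 0.0
    azimuth_range: Tuple[float, float] = (-180.0, 180.0)
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.circuit_fractions, dtype=float)
        if len(f) < 1 or np.any(np.diff(f) <= 0) or f[-1] != 1.0:
            raise ReachmapError("circuit fractions must be strictly increasing, ending at 1")
        lo, hi = self.azimuth_range
        if not -180.0 <= lo < hi <= 180.0:
            raise ReachmapError("azimuth_range must be an increasing sub-interval of [-180, 180]")


@dataclass
class EmgSurrogateModel:
    """Per-channel activation surfaces ``a(alpha, beta)`` in [0, 1]."""

    activation: Dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]]
    noise_sd: float = 0.0
    baseline: float = 0.0


def default_emg_surrogate(noise_sd: float = 0.05) -> EmgSurrogateModel:
    """Deltoid surrogate: activity rising with elevation in all three
    sections, with azimuth weighting favouring the section's plane
    (anterior at azimuth 0, middle laterally, posterior behind)."""

    def section(center_deg: float):
        c = np.radians(center_deg)

        def a(alpha, beta):
            al = np.radians(np.asarray(alpha, dtype=float))
            w = 0.6 + 0.4 * np.cos(al - c)
            return np.clip((np.asarray(beta, dtype=float) / 180.0) * w, 0.0, 1.0)

        return a

    return EmgSurrogateModel(
        activation={
            "emg_ant": section(0.0),
            "emg_mid": section(90.0),
            "emg_post": section(150.0),
        },
        noise_sd=noise_sd,
        baseline=2.0,
    )


def spherical_to_quaternion(alpha: float, beta: float) -> Tuple[float, float, float, float]:
    """Unit quaternion mapping the neutral arm direction to (alpha, beta).

    Composes a rotation of ``beta`` about the body y-axis (pure
    elevation in the anterior plane) with a rotation of ``alpha`` about
    the vertical z-axis; the axial-rotation degree of freedom is thereby
    fixed to a canonical value.  Feeding the result through the
    orientation pipeline with an identity reference recovers exactly
    (alpha, beta).
    """
    ha = 0.5 * np.radians(alpha)
    hb = 0.5 * np.radians(beta)
    ca, sa, cb, sb = np.cos(ha), np.sin(ha), np.cos(hb), np.sin(hb)
    return (ca * cb, -sa * sb, ca * sb, cb * sa)


def _spherical_to_quaternion_arrays(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    ha = 0.5 * np.radians(alpha)
    hb = 0.5 * np.radians(beta)
    ca, sa, cb, sb = np.cos(ha), np.sin(ha), np.cos(hb), np.sin(hb)
    return np.column_stack([ca * cb, -sa * sb, ca * sb, cb * sa])


def _jitter_angles(
    alpha: np.ndarray, beta: np.ndarray, sd_deg: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Add N(0, sd) angle-space jitter; azimuth wraps, elevation clips."""
    if sd_deg <= 0.0:
        return alpha, beta
    a = alpha + rng.normal(0.0, sd_deg, size=len(alpha))
    a = (a + 180.0) % 360.0 - 180.0
    a[a <= -180.0] = 180.0
    b = np.clip(beta + rng.normal(0.0, sd_deg, size=len(beta)), 0.0, 180.0)
    return a, b


def _canonical_sign(q: np.ndarray) -> np.ndarray:
    flip = q[:, 0] < 0
    q[flip] = -q[flip]
    return q


def simulate_trial(
    scenario: MotionScenario,
    emg: Optional[EmgSurrogateModel] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Generate a protocol trial: stream DataFrame plus ground truth.

    Circuit ``k`` sweeps the azimuth range once with elevation tracking
    ``fraction_k * B(alpha)`` — small envelope first, maximal last, per
    the clinical protocol (medial start, anterior, cranial, posterior,
    lateral, back to rest).  The returned DataFrame has columns
    ``t, qw, qx, qy, qz`` plus any EMG channels; the ground-truth dict
    carries the noise-free angles and the scenario parameters.
    """
    n_total = int(round(scenario.sample_rate * scenario.duration))
    if n_total < len(scenario.circuit_fractions):
        raise ReachmapError("duration too short for the requested circuits")
    rng = np.random.default_rng(scenario.seed)
    fractions = np.asarray(scenario.circuit_fractions, dtype=float)
    per = np.full(len(fractions), n_total // len(fractions))
    per[: n_total - per.sum()] += 1

    lo, hi = scenario.azimuth_range
    # the protocol starts from and returns to the neutral rest pose
    alphas: List[np.ndarray] = [np.zeros(1)]
    betas: List[np.ndarray] = [np.zeros(1)]
    for frac, n_k in zip(fractions, per):
        # sweep open at the lower end so azimuth stays inside (-180, 180]
        a = lo + (hi - lo) * (np.arange(1, n_k + 1) / n_k)
        alphas.append(a)
        betas.append(frac * np.asarray(scenario.envelope_function(a), dtype=float))
    alphas.append(np.zeros(1))
    betas.append(np.zeros(1))
    alpha = np.concatenate(alphas)
    beta = np.clip(np.concatenate(betas), 0.0, 180.0)
    n_total = len(alpha)
    t = np.arange(n_total) / scenario.sample_rate

    alpha_obs, beta_obs = _jitter_angles(alpha, beta, scenario.orientation_noise_sd, rng)
    q = _canonical_sign(_spherical_to_quaternion_arrays(alpha_obs, beta_obs))
    df = pd.DataFrame({"t": t, "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3]})

    truth = {
        "alpha": alpha.tolist(),
        "beta": beta.tolist(),
        "circuit_fractions": fractions.tolist(),
        "azimuth_range": [lo, hi],
        "sample_rate": scenario.sample_rate,
        "orientation_noise_sd": scenario.orientation_noise_sd,
        "seed": scenario.seed,
    }

    if emg is not None:
        for name, act in emg.activation.items():
            a_vals = np.clip(np.asarray(act(alpha, beta), dtype=float), 0.0, 1.0)
            noise = 1.0 + rng.normal(0.0, emg.noise_sd, size=n_total) if emg.noise_sd > 0 else 1.0
            df[name] = np.clip(emg.baseline + 100.0 * a_vals * noise, 0.0, None)
    return df, truth


@dataclass
class GimbalProgram:
    """Commanded (pitch, yaw) waypoints for the two-servo test stand.

    ``waypoints`` are (pitch, yaw, dwell_seconds) triples in degrees;
    the rig slews both axes simultaneously at ``slew_rate`` deg/s
    between waypoints, then dwells.
    """

    waypoints: Sequence[Tuple[float, float, float]]
    slew_rate: float = 60.0

    def __post_init__(self):
        for p, y, _ in self.waypoints:
            if not (-180.0 <= p <= 180.0 and -180.0 <= y <= 180.0):
                raise ReachmapError("waypoints must lie within the mechanical range [-180, 180]")
        if self.slew_rate <= 0:
            raise ReachmapError("slew rate must be positive")


def default_gimbal_program() -> GimbalProgram:
    """Elevation sweeps 0 -> 150 -> 0 in four azimuth planes, then a
    horizontal-abduction sweep at 90 deg elevation."""
    wp: List[Tuple[float, float, float]] = [(0.0, 0.0, 0.5)]
    for yaw in (0.0, 45.0, 90.0, 135.0):
        wp += [(0.0, yaw, 0.2), (150.0, yaw, 0.3), (0.0, yaw, 0.2)]
    wp += [(90.0, -90.0, 0.3), (90.0, 135.0, 0.3), (0.0, 0.0, 0.3)]
    return GimbalProgram(waypoints=wp)


def simulate_gimbal(
    program: GimbalProgram,
    noise_sd: float = 0.0,
    sample_rate: float = 100.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the servo-driven rig: quaternion stream + ground truth.

    Returns ``(stream, truth)`` where ``truth`` has columns
    ``t, pitch, yaw`` aligned sample-for-sample with the stream; pitch
    plays the role of elevation and yaw of azimuth.
    """
    rng = np.random.default_rng(seed)
    seg_t: List[np.ndarray] = []
    seg_p: List[np.ndarray] = []
    seg_y: List[np.ndarray] = []
    t0 = 0.0
    prev = program.waypoints[0]
    for i, (p, y, dwell) in enumerate(program.waypoints):
        if i > 0:
            move = max(abs(p - prev[0]), abs(y - prev[1])) / program.slew_rate
            n = max(int(np.ceil(move * sample_rate)), 1)
            frac = np.arange(1, n + 1) / n
            seg_t.append(t0 + frac * move)
            seg_p.append(prev[0] + frac * (p - prev[0]))
            seg_y.append(prev[1] + frac * (y - prev[1]))
            t0 += move
        n_dwell = max(int(np.round(dwell * sample_rate)), 1)
        tt = t0 + np.arange(1, n_dwell + 1) / sample_rate
        seg_t.append(tt)
        seg_p.append(np.full(n_dwell, p))
        seg_y.append(np.full(n_dwell, y))
        t0 = tt[-1]
        prev = (p, y, dwell)
    pitch = np.concatenate(seg_p)
    yaw = np.concatenate(seg_y)
    t = np.concatenate(seg_t)
    # re-time uniformly to the sample grid to keep timestamps strictly increasing
    t = np.arange(len(t)) / sample_rate

    yaw_obs, pitch_obs = _jitter_angles(yaw, pitch, noise_sd, rng)
    q = _canonical_sign(_spherical_to_quaternion_arrays(yaw_obs, pitch_obs))
    stream = pd.DataFrame(
        {"t": t, "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3]}
    )
    truth = pd.DataFrame({"t": t, "pitch": pitch, "yaw": yaw})
    return stream, truth
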