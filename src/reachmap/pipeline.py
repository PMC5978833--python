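"""End-to-end analysis: stream -> workspace + EMG trial result, and the
gimbal validation harness.

``analyze_stream`` glues the modules together: quaternion samples are
converted to reference-relative spherical poses, the maximal envelope
and its surface area, region occupancy and per-plane maxima are
extracted, and any EMG channels present are RMS-smoothed, normalized to
the within-trial MVC and binned over the workspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import emg as emg_mod
from .envelope import (
    EnvelopeProfile,
    PlaneMaxima,
    RegionPartition,
    build_envelope,
    plane_maxima,
    region_counts,
    surface_area,
)
from .errors import ReachmapError
from .io import AnalysisConfig, emg_channels_present
from .orientation import PoseTrace, QuaternionSample, stream_to_poses
from .simulate import GimbalProgram, simulate_gimbal

#: Bench-test acceptance thresholds for the orientation sensor, degrees.
ELEVATION_ERROR_LIMIT = 3.0
AZIMUTH_ERROR_LIMIT = 2.0


@dataclass
class TrialAnalysis:
    """Everything computed from one stream."""

    poses: PoseTrace
    envelope: EnvelopeProfile
    surface_area_deg2: float
    area_mode: str
    maxima: PlaneMaxima
    region_sample_counts: Dict[str, int]
    partition: RegionPartition
    emg_series: Dict[str, emg_mod.EmgSeries]
    emg_map: Optional[emg_mod.EmgMap]
    emg_region_summary: Optional[Dict[str, dict]]
    emg_channel_means: Dict[str, float]


def partition_from_config(config: AnalysisConfig) -> RegionPartition:
    return RegionPartition(
        elevation_split=config.elevation_split,
        medial=config.medial_sector,
        lateral=config.lateral_sector,
        posterior=config.posterior_sector,
    )


def poses_from_stream(df: pd.DataFrame, config: AnalysisConfig) -> PoseTrace:
    samples = [
        QuaternionSample.create(t, qw, qx, qy, qz, tol=config.norm_tolerance)
        for t, qw, qx, qy, qz in df[["t", "qw", "qx", "qy", "qz"]].itertuples(index=False)
    ]
    if isinstance(config.reference, str):
        reference = samples[0]
    else:
        reference = QuaternionSample.create(0.0, *config.reference)
    return stream_to_poses(samples, reference, config.arm_direction)


def analyze_stream(
    df: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> TrialAnalysis:
    """Run the full pipeline on one stream DataFrame."""
    config = config or AnalysisConfig()
    poses = poses_from_stream(df, config)
    part = partition_from_config(config)
    env = build_envelope(poses, config.bin_width)
    area = surface_area(env, config.area_mode)
    maxima = plane_maxima(
        poses, config.plane_tolerance, config.horizontal_band, part
    )
    counts = region_counts(poses, part)

    series: Dict[str, emg_mod.EmgSeries] = {}
    for name in emg_channels_present(df):
        raw = emg_mod.EmgSeries(t=df["t"].to_numpy(float), raw=df[name].to_numpy(float))
        series[name] = emg_mod.normalize_mvc(
            emg_mod.rectify_rms(raw, config.rms_window)
        )
    emg_map = summary = None
    if series:
        emg_map = emg_mod.emg_workspace_map(poses, series, config.emg_cell)
        summary = emg_mod.region_emg_summary(emg_map, part)
    channel_means = {
        name: float(np.mean(s.pct_mvc)) for name, s in series.items()
    }
    return TrialAnalysis(
        poses=poses,
        envelope=env,
        surface_area_deg2=area,
        area_mode=config.area_mode,
        maxima=maxima,
        region_sample_counts=counts,
        partition=part,
        emg_series=series,
        emg_map=emg_map,
        emg_region_summary=summary,
        emg_channel_means=channel_means,
    )


@dataclass
class GimbalValidationResult:
    """Per-repeat orientation errors against the rig's commanded angles.

    ``max_elevation_error`` / ``max_azimuth_error`` are maxima of the
    absolute per-sample differences between recovered and commanded
    angles in degrees (azimuth on the circle, excluding samples whose
    commanded elevation is below ``min_elevation`` where azimuth is
    geometrically undefined).  ``passed`` applies the bench acceptance
    thresholds of 3 deg elevation / 2 deg azimuth.
    """

    max_elevation_error: float
    max_azimuth_error: float
    elevation_limit: float
    azimuth_limit: float
    passed: bool
    n_samples: int


def validate_gimbal_stream(
    stream: pd.DataFrame,
    truth: pd.DataFrame,
    min_elevation: float = 1.0,
) -> GimbalValidationResult:
    """Compare pipeline-recovered angles with the commanded schedule."""
    config = AnalysisConfig(reference=(1.0, 0.0, 0.0, 0.0))
    poses = poses_from_stream(stream, config)
    if len(poses) != len(truth):
        raise ReachmapError("stream and ground truth are not aligned")
    elev_err = np.abs(poses.beta - truth["pitch"].to_numpy(float))
    yaw = truth["yaw"].to_numpy(float)
    az = (poses.alpha - yaw + 180.0) % 360.0 - 180.0
    defined = truth["pitch"].to_numpy(float) >= min_elevation
    max_az = float(np.max(np.abs(az[defined]))) if defined.any() else 0.0
    max_el = float(np.max(elev_err))
    return GimbalValidationResult(
        max_elevation_error=max_el,
        max_azimuth_error=max_az,
        elevation_limit=ELEVATION_ERROR_LIMIT,
        azimuth_limit=AZIMUTH_ERROR_LIMIT,
        passed=(max_el <= ELEVATION_ERROR_LIMIT) and (max_az <= AZIMUTH_ERROR_LIMIT),
        n_samples=len(poses),
    )


def run_gimbal_validation(
    program: Optional[GimbalProgram] = None,
    noise_sd: float = 0.0,
    repeats: int = 3,
    seed: int = 0,
) -> list:
    """Simulate the bench test (three repeats by protocol) and validate
    each repeat's recovered angles against the commanded schedule."""
    from .simulate import default_gimbal_program

    program = program or default_gimbal_program()
    results = []
    for k in range(repeats):
        stream, truth = simulate_gimbal(program, noise_sd=noise_sd, seed=seed + k)
        results.append(validate_gimbal_stream(stream, truth))
    return results
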