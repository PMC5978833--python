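"""CSV stream reading/writing and JSON analysis configuration.

Stream dialect: one row per sample, header required, UTF-8, decimal
point — ``t,qw,qx,qy,qz[,emg_ant,emg_mid,emg_post]`` with any subset of
the three EMG channels present (the clinical protocol records one
deltoid section per repeat).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import pandas as pd

from .emg import CHANNELS, DEFAULT_RMS_WINDOW
from .errors import ConfigError, ReachmapError

REQUIRED_COLUMNS = ("t", "qw", "qx", "qy", "qz")


def read_stream(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample stream CSV; validates required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ReachmapError(f"stream {path}: missing columns {missing}")
    if df.empty:
        raise ReachmapError(f"stream {path}: no samples")
    return df


def write_stream(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


def emg_channels_present(df: pd.DataFrame) -> List[str]:
    return [c for c in CHANNELS if c in df.columns]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their protocol defaults.

    ``reference`` selects the neutral-pose orientation: the string
    ``"first_sample"`` (the stream starts at rest) or an explicit
    ``[qw, qx, qy, qz]`` quaternion.
    """

    bin_width: float = 5.0
    area_mode: str = "planar"
    elevation_split: float = 90.0
    medial_sector: Tuple[float, float] = (-180.0, 0.0)
    lateral_sector: Tuple[float, float] = (0.0, 120.0)
    posterior_sector: Tuple[float, float] = (120.0, 180.0)
    plane_tolerance: float = 10.0
    horizontal_band: float = 10.0
    rms_window: float = DEFAULT_RMS_WINDOW
    emg_cell: float = 10.0
    arm_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    reference: Union[str, Sequence[float]] = "first_sample"
    norm_tolerance: float = 1e-3

    def __post_init__(self):
        if self.area_mode not in ("planar", "solid_angle"):
            raise ConfigError(f"unknown area_mode {self.area_mode!r}")
        if self.bin_width <= 0 or 360.0 % self.bin_width != 0.0:
            raise ConfigError("bin_width must be positive and divide 360")
        if not 0.0 < self.elevation_split < 180.0:
            raise ConfigError("elevation_split must lie in (0, 180)")
        if isinstance(self.reference, str):
            if self.reference != "first_sample":
                raise ConfigError(
                    "reference must be 'first_sample' or a [qw,qx,qy,qz] quaternion"
                )
        elif len(tuple(self.reference)) != 4:
            raise ConfigError("explicit reference quaternion needs 4 elements")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "AnalysisConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(payload)
        for key in ("medial_sector", "lateral_sector", "posterior_sector"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "arm_direction" in kwargs:
            kwargs["arm_direction"] = tuple(kwargs["arm_direction"])
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
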