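"""Surface-EMG processing: rectification, RMS smoothing, MVC
normalization, and binning of muscle activity over the workspace.

The device records up to three deltoid channels (anterior, middle,
posterior) synchronized sample-for-sample with the orientation stream.
The raw signal is rectified and smoothed with a centered moving RMS
window (default 100 ms at 100 Hz), then expressed as percent of the
Maximum Voluntary Contraction — here, by protocol, the maximum RMS
value the channel reaches within the trial, so every non-degenerate
channel attains 100 %MVC at least once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .envelope import REGION_LABELS, RegionPartition, classify_region
from .errors import DegenerateChannelError, ReachmapError, TimestampMismatchError
from .orientation import PoseTrace

CHANNELS = ("emg_ant", "emg_mid", "emg_post")

#: Default RMS smoothing window in seconds (10 samples at 100 Hz).
DEFAULT_RMS_WINDOW = 0.1


@dataclass
class EmgSeries:
    """One muscle channel: raw signal plus derived envelopes."""

    t: np.ndarray
    raw: np.ndarray
    rms: Optional[np.ndarray] = None
    pct_mvc: Optional[np.ndarray] = None


def rectify_rms(series: EmgSeries, window: float = DEFAULT_RMS_WINDOW) -> EmgSeries:
    """Rectify and smooth ``raw`` with a centered moving-RMS window.

    ``window`` is in seconds and must span at least 2 sample intervals;
    the window is truncated at the stream edges.  Squaring performs the
    rectification implicitly, so the output is sign-invariant.
    """
    t = np.asarray(series.t, dtype=float)
    raw = np.asarray(series.raw, dtype=float)
    if len(t) < 2:
        raise ReachmapError("need at least 2 samples to smooth")
    dt = float(np.median(np.diff(t)))
    win = int(round(window / dt))
    if win < 2:
        raise ReachmapError(
            f"RMS window {window:g}s is shorter than 2 sample intervals (dt={dt:g}s)"
        )
    sq = pd.Series(raw**2)
    mean_sq = sq.rolling(window=win, center=True, min_periods=1).mean().to_numpy()
    return EmgSeries(t=t, raw=raw, rms=np.sqrt(mean_sq))


def normalize_mvc(series: EmgSeries) -> EmgSeries:
    """Express the RMS envelope as percent of its within-trial maximum."""
    if series.rms is None:
        raise ReachmapError("run rectify_rms before MVC normalization")
    peak = float(np.max(series.rms))
    if peak <= 0.0:
        raise DegenerateChannelError("all-zero RMS envelope; cannot normalize")
    return EmgSeries(
        t=series.t,
        raw=series.raw,
        rms=series.rms,
        pct_mvc=100.0 * series.rms / peak,
    )


@dataclass
class EmgMap:
    """Workspace-binned muscle activity.

    ``cells`` is a long-format table with one row per (azimuth bin,
    elevation bin, channel): columns ``alpha_bin``, ``beta_bin`` (cell
    centers, degrees), ``channel``, ``mean_pct_mvc``, ``n``.
    """

    cell: float
    cells: pd.DataFrame


def _bin_centers(values: np.ndarray, lo: float, cell: float, nbins: int) -> np.ndarray:
    idx = np.clip(np.ceil((values - lo) / cell).astype(int) - 1, 0, nbins - 1)
    return lo + cell * (idx + 0.5)


def emg_workspace_map(
    poses: PoseTrace,
    emg: Mapping[str, EmgSeries],
    cell: float = 10.0,
) -> EmgMap:
    """Bin %MVC activity over the (azimuth, elevation) workspace grid.

    Poses and EMG must share timestamps (the hardware synchronizes the
    streams); a mismatch beyond half a sample interval is an error.
    Cells with no samples are simply absent from the table, and per
    channel the sample counts across cells sum to the stream length.
    """
    if 360.0 % cell != 0.0 or 180.0 % cell != 0.0:
        raise ReachmapError("cell size must divide both 360 and 180 degrees")
    half_dt = 0.5 * float(np.median(np.diff(poses.t))) if len(poses) > 1 else 0.0
    frames = []
    n_az = int(round(360.0 / cell))
    n_el = int(round(180.0 / cell))
    for name, series in emg.items():
        if series.pct_mvc is None:
            raise ReachmapError(f"channel {name}: normalize to %MVC first")
        if len(series.t) != len(poses) or (
            len(poses) > 1 and np.max(np.abs(series.t - poses.t)) > half_dt
        ):
            raise TimestampMismatchError(
                f"channel {name}: EMG timestamps do not match pose timestamps"
            )
        frames.append(
            pd.DataFrame(
                {
                    "alpha_bin": _bin_centers(poses.alpha, -180.0, cell, n_az),
                    "beta_bin": _bin_centers(poses.beta, 0.0, cell, n_el),
                    "channel": name,
                    "pct_mvc": series.pct_mvc,
                }
            )
        )
    if not frames:
        raise ReachmapError("no EMG channels supplied")
    long = pd.concat(frames, ignore_index=True)
    cells = (
        long.groupby(["alpha_bin", "beta_bin", "channel"], as_index=False)
        .agg(mean_pct_mvc=("pct_mvc", "mean"), n=("pct_mvc", "size"))
        .sort_values(["channel", "alpha_bin", "beta_bin"], ignore_index=True)
    )
    return EmgMap(cell=float(cell), cells=cells)


def region_emg_summary(
    emg_map: EmgMap, part: RegionPartition = RegionPartition()
) -> Dict[str, dict]:
    """Sample-count-weighted mean %MVC per region, per channel.

    Returns ``{channel: {"region_means": {I..VI: mean or None},
    "max_region": label}}`` where ``max_region`` is the region of
    highest mean activity for that channel.
    """
    df = emg_map.cells
    if df.empty:
        raise ReachmapError("EMG map is empty")
    region = classify_region(
        df["alpha_bin"].to_numpy(), df["beta_bin"].to_numpy(), part
    )
    df = df.assign(region=region)
    out: Dict[str, dict] = {}
    for channel, grp in df.groupby("channel"):
        means = {}
        for lab in REGION_LABELS:
            sub = grp[grp["region"] == lab]
            if len(sub) == 0:
                means[lab] = None
            else:
                w = sub["n"].to_numpy()
                means[lab] = float(np.average(sub["mean_pct_mvc"].to_numpy(), weights=w))
        present = {k: v for k, v in means.items() if v is not None}
        out[str(channel)] = {
            "region_means": means,
            "max_region": max(present, key=present.get),
        }
    return out
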