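"""Static workspace figures: azimuth-elevation scatter with the maximal
envelope overlay, and colour-contour maps of %MVC muscle activity."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
from .emg import EmgMap
from .envelope import EnvelopeProfile
from .orientation import PoseTrace


def workspace_plot(
    poses: PoseTrace,
    envelope: Optional[EnvelopeProfile] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Azimuth vs elevation scatter of the trial with envelope overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(poses.alpha, poses.beta, ".", ms=1.5, color="0.55", label="samples")
    if envelope is not None:
        vis = envelope.visited
        ax.step(
            envelope.bin_centers[vis],
            envelope.beta_max[vis],
            where="mid",
            color="tab:red",
            lw=1.8,
            label="maximal envelope",
        )
    ax.set_xlabel("azimuth α (deg)")
    ax.set_ylabel("elevation β (deg)")
    ax.set_xlim(-180, 180)
    ax.set_ylim(0, 180)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def emg_map_plot(emg_map: EmgMap, channel: str, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Colour map of mean %MVC over the (azimuth, elevation) grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    cells = emg_map.cells[emg_map.cells["channel"] == channel]
    if cells.empty:
        raise ValueError(f"channel {channel!r} not present in the map")
    half = emg_map.cell / 2.0
    sc = ax.scatter(
        cells["alpha_bin"],
        cells["beta_bin"],
        c=cells["mean_pct_mvc"],
        s=(half * 4) ** 2,
        marker="s",
        cmap="viridis",
        vmin=0,
        vmax=100,
    )
    plt.colorbar(sc, ax=ax, label="mean %MVC")
    ax.set_xlabel("azimuth α (deg)")
    ax.set_ylabel("elevation β (deg)")
    ax.set_xlim(-180, 180)
    ax.set_ylim(0, 180)
    ax.set_title(channel)
    return ax


def save_figure(ax: plt.Axes, path: str) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
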