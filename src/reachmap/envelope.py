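"""Reachable-workspace envelope extraction and range-of-motion statistics.

The maximal voluntary workspace of the shoulder is summarized as the
outer boundary of arm elevation per azimuth direction: azimuth is binned
over ``(-180, 180]`` and each visited bin stores the maximum observed
elevation.  Two area readings of that envelope are supported:

* ``planar`` (default) — the area under the envelope in the
  azimuth-elevation chart, sum of ``beta_max * bin_width`` in deg²;
* ``solid_angle`` — the spherical-cap area actually swept on the unit
  sphere, ``sum(bin_width_rad * (1 - cos beta_max))`` steradians scaled
  by ``(180/pi)²`` to square degrees (full sphere = 41252.96 deg²).

The workspace is partitioned into six clinical regions: lower/higher
medial (I/II), lateral (III/IV) and posterior (V/VI) elevation, split at
a configurable elevation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ReachmapError
from .orientation import PoseTrace

#: Area of the full sphere in square degrees, 4*pi*(180/pi)^2.
FULL_SPHERE_DEG2 = 4.0 * 180.0**2 / np.pi

REGION_LABELS = ("I", "II", "III", "IV", "V", "VI")

REGION_NAMES = {
    "I": "lower medial elevation",
    "II": "higher medial elevation",
    "III": "lower lateral elevation",
    "IV": "higher lateral elevation",
    "V": "lower posterior elevation",
    "VI": "higher posterior elevation",
}


def _wrap_azimuth(alpha: np.ndarray) -> np.ndarray:
    """Wrap azimuth into (-180, 180]."""
    a = (np.asarray(alpha, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(a <= -180.0, 180.0, a)


@dataclass(frozen=True)
class EnvelopeProfile:
    """Per-azimuth-bin maximal elevation; NaN marks unvisited bins."""

    bin_width: float
    bin_centers: np.ndarray
    beta_max: np.ndarray

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.beta_max)

    def __post_init__(self):
        n = len(self.bin_centers)
        if n * self.bin_width != 360.0:
            raise ReachmapError("bins must tile 360 degrees of azimuth")
        if len(self.beta_max) != n:
            raise ReachmapError("bin_centers and beta_max length mismatch")


@dataclass(frozen=True)
class RegionPartition:
    """Partition of the workspace into the six clinical ROM regions.

    ``elevation_split`` separates "lower" from "higher" elevation
    (a pose is "higher" iff ``beta >= elevation_split``).  The azimuth
    sectors are half-open ``[lo, hi)`` intervals in degrees except that
    a sector reaching +180 includes it; together they must tile
    ``(-180, 180]``.  Defaults: medial ``(-180, 0)``, lateral
    ``[0, 120)``, posterior ``[120, 180]`` under the body-frame
    convention with anterior at azimuth 0 and lateral at +90.
    """

    elevation_split: float = 90.0
    medial: tuple = (-180.0, 0.0)
    lateral: tuple = (0.0, 120.0)
    posterior: tuple = (120.0, 180.0)

    def __post_init__(self):
        if not 0.0 < self.elevation_split < 180.0:
            raise ReachmapError("elevation_split must lie in (0, 180)")
        spans = sorted([self.medial, self.lateral, self.posterior])
        if spans[0][0] != -180.0 or spans[-1][1] != 180.0:
            raise ReachmapError("azimuth sectors must cover (-180, 180]")
        for (a, b), (c, _) in zip(spans, spans[1:]):
            if b != c or a >= b:
                raise ReachmapError("azimuth sectors must tile without overlap")

    def sector_of(self, alpha) -> np.ndarray:
        """'medial' / 'lateral' / 'posterior' per azimuth sample."""
        a = _wrap_azimuth(np.atleast_1d(alpha))
        out = np.empty(a.shape, dtype=object)
        for name, (lo, hi) in (
            ("medial", self.medial),
            ("lateral", self.lateral),
            ("posterior", self.posterior),
        ):
            mask = (a >= lo) & (a < hi) if hi < 180.0 else (a >= lo) & (a <= hi)
            out[mask] = name
        return out


@dataclass(frozen=True)
class PlaneMaxima:
    """Maximal elevation in the standard planes; None where unvisited (NA)."""

    max_flexion: Optional[float]
    max_abduction: Optional[float]
    max_extension: Optional[float]
    max_horizontal_abduction: Optional[float]


def azimuth_bin_index(alpha, bin_width: float) -> np.ndarray:
    """Index of the azimuth bin covering each sample; bins are
    ``(-180 + i*w, -180 + (i+1)*w]``."""
    a = _wrap_azimuth(alpha)
    n = int(round(360.0 / bin_width))
    idx = np.ceil((a + 180.0) / bin_width).astype(int) - 1
    return np.clip(idx, 0, n - 1)


def build_envelope(poses: PoseTrace, bin_width: float = 5.0) -> EnvelopeProfile:
    """Bin azimuth and keep the maximum elevation observed in each bin."""
    if 360.0 % bin_width != 0.0:
        raise ReachmapError("360 must be divisible by bin_width")
    if len(poses) == 0:
        raise ReachmapError("cannot build an envelope from an empty pose sequence")
    n = int(round(360.0 / bin_width))
    centers = -180.0 + bin_width * (np.arange(n) + 0.5)
    idx = azimuth_bin_index(poses.alpha, bin_width)
    beta_max = np.full(n, -np.inf)  # -inf seeds the running max; unvisited -> NaN
    np.maximum.at(beta_max, idx, poses.beta)
    beta_max[np.isinf(beta_max)] = np.nan
    return EnvelopeProfile(bin_width=float(bin_width), bin_centers=centers, beta_max=beta_max)


def surface_area(env: EnvelopeProfile, mode: str = "planar") -> float:
    """Workspace area of an envelope in square degrees.

    Unvisited bins contribute zero area in both modes.
    """
    visited = env.visited
    if not visited.any():
        raise ReachmapError("envelope has no visited bins")
    beta = env.beta_max[visited]
    if mode == "planar":
        return float(np.sum(beta * env.bin_width))
    if mode == "solid_angle":
        w_rad = np.radians(env.bin_width)
        sr = np.sum(w_rad * (1.0 - np.cos(np.radians(beta))))
        return float(sr * (180.0 / np.pi) ** 2)
    raise ReachmapError(f"unknown area mode {mode!r}")


def classify_region(
    alpha, beta, part: RegionPartition = RegionPartition()
) -> np.ndarray:
    """Assign each pose one of the six region labels I–VI.

    "Higher" means ``beta >= elevation_split``; the azimuth sector picks
    the medial/lateral/posterior column.  Total on valid poses: every
    sample receives exactly one label.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    sector = np.empty(alpha.shape, dtype=object)
    sector[:] = RegionPartition.sector_of(part, alpha)
    higher = beta >= part.elevation_split
    table = {
        ("medial", False): "I",
        ("medial", True): "II",
        ("lateral", False): "III",
        ("lateral", True): "IV",
        ("posterior", False): "V",
        ("posterior", True): "VI",
    }
    out = np.array([table[(s, bool(h))] for s, h in zip(sector, higher)], dtype=object)
    return out


def region_counts(
    poses: PoseTrace, part: RegionPartition = RegionPartition()
) -> dict:
    """Number of samples falling in each region."""
    labels = classify_region(poses.alpha, poses.beta, part)
    return {lab: int(np.sum(labels == lab)) for lab in REGION_LABELS}


def _angdiff(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0
    return np.where(d <= -180.0, 180.0, d)


def plane_maxima(
    poses: PoseTrace,
    plane_tolerance: float = 10.0,
    horizontal_band: float = 10.0,
    part: RegionPartition = RegionPartition(),
) -> PlaneMaxima:
    """Maximal elevation in the flexion / abduction planes, posterior
    extension, and the horizontal-abduction azimuth span.

    * flexion: max elevation among samples with azimuth within
      ``plane_tolerance`` of 0 (anterior plane);
    * abduction: likewise about +90 (lateral plane);
    * extension: max elevation among samples in the posterior sector;
    * horizontal abduction: the azimuth span (max - min on an unwrapped,
      continuity-preserving axis) of samples whose elevation lies within
      ``horizontal_band`` of 90, which can exceed 180.

    A plane with no qualifying samples yields ``None`` (reported as NA).
    """

    def _max_or_none(mask) -> Optional[float]:
        return float(np.max(poses.beta[mask])) if np.any(mask) else None

    flex = _max_or_none(np.abs(_angdiff(poses.alpha, 0.0)) <= plane_tolerance)
    abd = _max_or_none(np.abs(_angdiff(poses.alpha, 90.0)) <= plane_tolerance)
    ext = _max_or_none(part.sector_of(poses.alpha) == "posterior")

    horiz_mask = np.abs(poses.beta - 90.0) <= horizontal_band
    if np.any(horiz_mask):
        a = np.unwrap(poses.alpha[horiz_mask], period=360.0)
        # a full turn is the physical ceiling of the azimuth span
        horiz = float(min(np.max(a) - np.min(a), 360.0))
    else:
        horiz = None
    return PlaneMaxima(flex, abd, ext, horiz)


def cv_across_trials(values: Sequence[float]) -> float:
    """Coefficient of variation across repeat trials, in percent.

    100 x sample standard deviation (n-1 denominator) / mean.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ReachmapError("coefficient of variation needs at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ReachmapError("values must be finite")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ReachmapError("coefficient of variation undefined for zero mean")
    return float(100.0 * np.std(v, ddof=1) / mean)
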