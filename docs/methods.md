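# Methods

## Coordinate conventions

The body frame is right-handed with `+z` along the hanging arm in the
neutral pose, `+x` anterior and `+y` toward the subject's lateral side.
Elevation `β` is the angle between the current arm direction and neutral
`+z` (`β = 0` at rest); azimuth `α = atan2(y, x)` is the direction of the
elevated arm around the vertical axis, with the flexion plane at `α = 0`,
the abduction plane at `α = +90°` and `|α| → 180°` posterior. The azimuth
uses the two-argument arctangent so all four quadrants are covered; it
reduces to `atan(y/x)` anteriorly. These axis assignments are this
package's documented convention — clinical azimuth conventions vary, and a
signed medial-negative/lateral-positive azimuth was chosen over a 0–360
measure because span-type metrics (horizontal abduction) are computed by
unwrapping anyway.

Quaternions are canonicalized on input (`qw ≥ 0`, renormalized); a norm
deviating from 1 by more than `1e-3` (configurable) marks a corrupt sample
and aborts with the offending timestamp. The rotation-matrix inverse is
taken as the transpose, exact for rotations. Axial rotation of the humerus
about its long axis leaves the arm direction unchanged and is therefore
invisible in the output by construction.

## Envelope and area

Azimuth is divided into bins of `bin_width` (default 5°) tiling
`(−180°, 180°]`; each visited bin keeps the maximum observed elevation.
Unvisited bins contribute zero area (no interpolation by default —
conservative for sparse coverage). Two area definitions are reported
because "deg²" is genuinely ambiguous for a spherical workspace:

* `planar` (default): `Σ β_max · bin_width`, the area under the envelope in
  the α–β chart. This is what a 2-D plot of the data shows and is the
  default output.
* `solid_angle`: `Σ Δα_rad · (1 − cos β_max)` steradians × `(180/π)²`, the
  spherical-cap area actually swept; bounded by the full sphere,
  4·180²/π ≈ 41252.96 deg².

The mode is recorded in every result. Note the max-envelope step function
is an upward-biased area estimator for smooth envelopes: the bias per bin is
roughly `|B′| · bin_width / 2`, about 1.4% of the default healthy preset's
area at 5° bins and under 0.5% at 2° bins. Round-trip fidelity checks
therefore use 2° bins.

## Regions and plane maxima

The six ROM regions split elevation at `elevation_split` (default 90°;
"higher" means `β ≥` split) and azimuth into medial `(−180°, 0°)`, lateral
`[0°, 120°)` and posterior `[120°, 180°]` sectors — configurable, since the
sector boundaries are a clinical convention rather than a measurement.
Plane maxima take the maximum elevation within `plane_tolerance` (default
10°) of the flexion/abduction planes, the maximum elevation anywhere in the
posterior sector (extension), and the azimuth span of samples within
`horizontal_band` (default 10°) of 90° elevation, unwrapped along the
trajectory (nearest branch) so spans beyond 180° are representable, and
capped at 360° — a full turn — because nearest-branch unwrapping over many
circuits could otherwise accumulate artificial extra turns.

## EMG chain

Raw EMG is squared, averaged over a centered moving window (default 100 ms
= 10 samples at 100 Hz, truncated at the stream edges) and square-rooted;
squaring performs the rectification. No additional filtering is applied by
default — the window length is the only smoothing parameter, and it must
span at least two sample intervals. Normalization divides by the
within-trial maximum RMS value (the protocol's MVC reference), so %MVC is
scale-invariant in the raw signal, lies in [0, 100] and attains 100 at
least once per channel; an identically zero channel is an error. Using the
within-trial maximum as MVC is a deliberate protocol simplification: it
does not measure absolute activation capacity, only relative intensity
within a trial. Any subset of the three deltoid channels may be present
(the protocol records sections sequentially across repeats).

Workspace maps average %MVC over square (α, β) cells (default 10°);
sample counts are conserved, and region summaries weight cell means by
sample count, so the count-weighted mean over regions recovers the global
mean exactly.

## Simulator

The simulator is the stand-in for the hardware and defines the test
conditions.

* **Protocol trials**: four consecutive circuits sweep the azimuth range at
  constant angular speed, with elevation tracking fractions
  (0.25, 0.5, 0.75, 1.0) of the envelope `B(α)`, starting from and
  returning to the neutral rest pose; default 60 s at 100 Hz. The healthy
  preset is the smooth two-harmonic profile
  `B(α) = 107.5 + 45 cos α + 30 sin α − 2.5 cos 2α`, anchored at ~150°
  flexion, ~140° abduction, ~80° medial and ~60° posterior elevation —
  face-valid for a healthy maximal workspace without claiming to reproduce
  any subject. The frozen preset scales it by 0.55, caps it at 70° and
  restricts azimuth to (−100°, 100°), which reproduces the clinical
  signature of absent extension/horizontal-abduction measurements.
* **Orientation noise** is Gaussian jitter added in angle space (azimuth
  wrapped, elevation clipped) before quaternion synthesis, so the stated sd
  is directly the angular read-out error. A composed-random-rotation model
  was considered and rejected: it makes azimuth read-out error diverge as
  `1/sin β` near zero elevation, which would make bench-style azimuth error
  bounds unattainable at any realistic noise level.
* **Gimbal rig**: waypoint programs (pitch, yaw, dwell) slewed at 60°/s,
  sampled at 100 Hz, with per-sample ground truth. The default program
  sweeps elevation 0→150→0 in four azimuth planes plus one
  horizontal-abduction sweep at 90° elevation; each bench run is repeated
  three times. The validation report compares pipeline-recovered angles
  with the commanded schedule and applies pass thresholds of 3° (elevation)
  and 2° (azimuth); samples below 1° commanded elevation are excluded from
  the azimuth error because azimuth is geometrically undefined at the pole.
* **EMG surrogate**: per-channel activation `a(α, β) ∈ [0, 1]` increasing
  with elevation and weighted toward each section's plane (anterior 0°,
  middle 90°, posterior 150°), scaled to 100 with multiplicative Gaussian
  noise and a small baseline, clipped at zero.

Everything is deterministic under a fixed seed (same seed → byte-identical
streams). What the simulator does **not** model: scapulohumeral rhythm and
multi-segment kinematics, torso compensation, sensor drift or magnetic
disturbance, servo dynamics, electrode placement variability, or
physiological EMG spectra (the surrogate is an amplitude model only).
Passing round-trip tests therefore demonstrates the correctness of the
analysis chain, not the behavior of real sensors on real shoulders.

## Cohort statistics

Subjects with repeat trials enter group statistics through their
per-subject mean; group dispersion is the sample standard deviation (n−1),
which is the convention that reproduces the published healthy-cohort
spread from its per-subject values (the population formula does not).
Repeatability is the coefficient of variation, 100·SD/mean, across a
subject's repeats. Single-subject groups get SD 0 by convention, with a
warning. Group comparisons report differences and ratios only — no
inferential statistics are defined for this design. Reports round to
integers (half-to-even) in human-readable tables; machine-readable JSON
keeps full precision. Metrics that are absent for a trial (a plane never
visited) propagate as NA/null rather than zero.

## Numerical notes and limitations

* `arccos` arguments are clipped to [−1, 1] to absorb rounding.
* At exactly `β = 0` the azimuth is undefined; `atan2(0, 0) = 0` is
  returned and downstream consumers treat near-zero elevation specially
  where it matters (gimbal azimuth error).
* The azimuth branch point maps to +180° so the domain is exactly
  `(−180°, 180°]`.
* Envelope bins are half-open `(lo, hi]`; the elevation split assigns the
  boundary to "higher".
* The planar area definition is chart area, not spherical area; comparing
  planar numbers across subjects assumes comparable azimuth coverage.
  Areas are not normalized to arm length.
* One IMU cannot separate glenohumeral from scapulothoracic contributions;
  results describe whole-arm pointing direction.
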