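# Methods

## Data model

Every measurement carries a stamp: global time in integer milliseconds and
along-track odometer position in integer millimetres — the encoder/clock
granularity of the rig is the natural quantum, and sub-resolution values
are rounded half-up at generation. A sensor mounted at longitudinal offset
*o* records the ground point *p − o* when the odometer reads *p*;
`align_stream` removes the offset so all sensors share one ground
coordinate. All position intervals are half-open `[start, end)`, which
makes adjacent plot slices partition a stream without double counting.
Light-barrier indices are 0-based from the bottom of the lower curtain;
the upper curtain continues the index range 288–575, so one linear stacked
index covers both curtains and barrier *i* sits at
`ground_clearance + i × 2.5 mm` above ground.

The raw store is a directory of per-sensor tables (CSV for scalar sensors,
NumPy `.npz` containers or optionally per-frame CSV for matrix sensors)
plus a JSON manifest with sensor specs and a schema version — a desk-scale,
server-free stand-in for the per-sensor database tables of the original
acquisition system. Persistence is bit-exact (floats are written with
`%.17g` and parsed in round-trip mode). A single logical clock is assumed;
no clock-synchronisation machinery is modelled.

## Simulator

The canopy of a row is a 1-D profile over integer ground millimetres:
inside a plot, each column is plant with probability equal to the plot's
coverage density, and plant columns draw a surface height from
Normal(true_height, σ_h). The ground drifts sinusoidally under the curtain
(terrain), and the top-view mount tracks each plot's height at a constant
500 mm canopy clearance, emulating the operator's height adjustment as a
per-plot constant. There is no 3-D plant architecture, no growth dynamics,
no lodging, and no radiometric/BRDF modelling — the 1-D profile is exactly
what the per-plot order statistics consume, nothing more.

Forward models per sensor:

* **Light curtains** — barrier interrupted iff a plant column reaches its
  height; sensor noise is Bernoulli *dropout* of interrupted readings
  (default 2 %), i.e. missed detections of thin organs. Symmetric flips
  were rejected: any uniform false-trigger rate plants ghost readings at
  the top of the 576-index range and makes the pooled 1 %-highest height
  statistic diverge by construction, which no working industrial light
  barrier exhibits.
* **LDS1/ToF1 (top)** — mount height minus canopy height over plant,
  ground hit over gaps, Gaussian noise (σ 8 mm laser, 15 mm ToF pixels);
  ToF frames replicate the column profile across the 50 × 64 grid.
* **LDS2/ToF2 (side)** — near return off the outer plant rows (400 mm),
  deeper returns through canopy gaps (+600 mm), far return (1500 mm)
  between plots.
* **LDS3 (ground)** — curtain-to-ground distance following the terrain,
  with occasional short returns off low plant parts (3 % of plant columns,
  50–150 mm short); the 3 %-maximum rule in the ground profile is exactly
  what suppresses them.
* **HSI** — per line, `round(coverage × 252)` plant pixels carry a plant
  endmember whose 1450 nm water-absorption dip scales with moisture, the
  rest carry a soil endmember; band-wise Gaussian noise (σ 3 counts),
  quantised to the sensor's native byte counts. The two endmembers subtend
  ~0.28 rad; plant spectra across the whole moisture range stay within
  ~0.06 rad of the default reference, so the default SAM threshold of
  0.15 rad sits midway between the classes.

Frame stamps advance by cumulative half-up rounding,
`stamp_j = round(j·1000/f)` ms and `round(j·speed/f)` mm, which keeps
position and time physically consistent for the 1000 Hz sensors whose
per-frame step is below the 1 mm position quantum.

All randomness flows from one master seed through named child seeds per
(row, sensor, repetition). The canopy and terrain realisation uses a child
seed independent of the repetition index: the plants are a property of the
field, so repeated passes share them and differ only in sensor noise.
`simulate_repeated_pass(..., rep_noise=0)` therefore yields bit-identical
passes. Noise magnitudes are not documented for the original rig; the
defaults above were chosen once as realistic for the sensor classes
involved and produce technical repeatability in the high range reported
for field platforms of this type (R_w² ≳ 0.97 on the default synthetic
conditions). Because the synthetic canopy lacks wind motion, operator
variability and genuine plant re-arrangement between passes, synthetic
repeatability is optimistic; passing these checks demonstrates the
correctness of the processing chain, not field-level precision.

## Plot segmentation

The lower curtain's interrupted fraction is smoothed over a 100 mm
position window, thresholded at 0.05 with hysteresis (sub-300 mm dips are
closed), and candidates shorter than 1000 mm are discarded. Boundaries are
then refined to the first/last *plant* column — a column whose own
interrupted fraction exceeds the threshold — because the smoothing window
widens each candidate by up to half a window and isolated noise readings
must not move a boundary. Plot identities come strictly from the field
plan in traversal order; a count mismatch raises an operator-facing error
rather than attempting a repair, mirroring the manual row-wise recording
procedure. On noise-free simulations boundaries are exact to one curtain
column spacing (3 mm at 0.5 m/s and 170 Hz).

## Trait features

All extreme-fraction statistics use the count rule k = max(1, ⌈f·N⌉) with
a stable sort for deterministic tie handling; the rule guarantees a
non-empty selection at any N. The light-curtain height pools interrupted
(column, barrier) readings of both curtains across the whole plot and
averages the k highest stacked indices, each converted to height above
ground via the 10-cm-increment ground-distance profile of its column (a
step function; no interpolation within increments). Per-column pooling —
taking only each column's top barrier — is available as a configuration
switch (`lc_per_column`); pooled is the default reading of the plot-level
rule. Both curtains use the same ground profile. A trailing partial
increment keeps its own value when it holds at least 10 samples and is
merged into its neighbour otherwise; empty increments are interpolated
from neighbours and logged.

Because the 1 %-highest rule measures the upper canopy envelope, its
estimate sits above the *mean* canopy height by roughly the upper tail of
the within-plot height distribution (≈ +2σ_h under the simulator's
Gaussian canopy). Under noise-free, uniform-canopy conditions the
estimate equals the truth to within one barrier pitch; under realistic
conditions the offset is proportional-ish and is absorbed by the
through-origin calibration.

Per-parameter failures (e.g. an empty depth-camera slice) become NaN
records, never pipeline aborts; downstream statistics drop null pairs per
group and count them — the multi-sensor redundancy of the rig makes
partial results useful.

## Calibration statistics

The trait calibration is regression through the origin, b = Σxy/Σx²,
exactly as the field procedure defines it; an intercept mode exists behind
a flag for diagnostics only. MRE_w normalises by the first repetition, so
the statistic is deliberately asymmetric in repetition order; the stored
repetition index defines the order. Both r² statistics are squared Pearson
correlations; constant sequences make them undefined and are reported as
null rather than forced to a number. Calibration pools all repetitions
(averaged per plot) rather than fitting per measurement campaign.

## Problem sizes and numerical choices

End-to-end checks use 50 noise-free plots (5 rows × 10 plots of 1.2 m) for
parameter recovery and 24 plots (2 rows × 12) for the repeatability
report. These sizes were chosen as the smallest at which the statistics
are meaningful — 1.2 m plots still hold ~400 curtain columns, 12 ToF
frames and 240 hyperspectral lines each; at the 100 Hz line rate a
hyperspectral frame arrives every 5 mm, so data volume grows at ~16 MB per
plot-metre and longer plots add volume, not information, to these checks.
Oracle-equivalence checks run 1000 random instances per statistic at
tolerance 1e-12 against independently coded brute-force implementations.
Angles are computed with the cosine clipped to [−1, 1] before arccos;
zero-norm spectra are classified as soil and logged rather than raising
inside a frame loop.

## Known limitations

* The simulator's repeatability is optimistic (no wind, no operator
  variance); its calibration residuals reflect the envelope-vs-mean height
  definition gap, not instrument accuracy.
* Side-view forward models are coarse (three-level returns), adequate for
  exercising the mean-based penetration statistics only.
* Colour camera, webcam and GPS payloads are carried as metadata concepts
  only; no algorithms are defined for them.
* No moisture or nitrogen calibration from the hyperspectral data is
  included — only SAM-based coverage density.
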