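# Methods

## Scope and model of the data

chipcyte analyses single 2-D multi-channel fluorescence fields (one
grayscale plane per channel, 16-bit counts, identical dimensions).  Each
field is processed independently; multi-field acquisitions are summed at the
measurement level (`sum_count`, `sum_area_covered`), never stitched.
Channels are addressed by biological role — `nuclear`, `pan_cell`, `gfp`,
`rfp` — with the plane-to-role mapping supplied by the user, since
acquisition order varies by instrument.  Intensities are never rescaled on
load; 8-bit input is widened to the 16-bit range value-for-value.

Coordinates are row-major with origin at the top-left; `x` is the column
index, 0-based.  Reported X positions are object centroids (the
bounding-box alternative was rejected as noisier under partial occlusion
at field edges).

## Segmentation operators

### Kernel-based object segmentation (seeds)

Parameters: `kernel_size` (odd, px) and `sensitivity` s ∈ (0, 100].
Sensitivity maps to the minimum object brightness-to-background ratio

    r(s) = 1 + (100 − s) / 50        (s = 50 → r = 2)

so a higher sensitivity accepts lower-contrast objects.  The decision rule
at each pixel is

    (mean_k − floor)  ≥  r(s) · max(bg − floor, 1)

where `mean_k` is the plane mean-filtered at the kernel scale, `bg` the
local background (below), and `floor = min(bg)` the dark level of the image
(camera offset / empty regions such as the PDMS posts).  Measuring both
sides above the floor keeps the ratio semantics and makes the criterion
exactly invariant under constant additive offsets; a perfectly flat plane
yields an empty mask.

**Background estimate.**  `bg` is the pointwise minimum of window medians at
3× and 9× the kernel size.  A single 3k-window median overshoots wherever
touching nuclei cover more than half of the window (a clumped pair of
~800 px² nuclei covers ~80% of a 45 px window), which silently erases
detections; the 9k median is uncontaminated there, and the minimum keeps
whichever estimate is lower.  Both medians are computed on a 4×-decimated
grid and bilinearly upsampled — within ~1% of the full-resolution filter at
a small fraction of the cost, and exactly offset-equivariant.  A low
quantile instead of the median was rejected: on low-count Poisson
backgrounds the 25th percentile underestimates the background by ~50% and
floods the mask with noise.

### Seed-started nuclear segmentation

Parameters: `min_target_area` (px²) and `sensitivity` s.  Each seed object
is a watershed marker; regions grow on the inverted 5-px-smoothed nuclear
plane, restricted to pixels whose **raw** intensity satisfies

    (I − floor) ≥ (1 + (100 − s)/100) · max(bg − floor, 1)     (s = 15 → 1.85×)

Gating growth on the raw intensity rather than the smoothed plane matters:
the smoothing halo otherwise inflates grown nuclei ~25% beyond the stop
criterion.  The smoothed plane serves only as the watershed topography.
After growth each candidate is opened with a disc of radius 2 (the rounded
shape prior); if opening fragments a candidate, the piece containing its
seed is kept.  Candidates with area strictly below `min_target_area` are
discarded, as are candidates that lost every seed pixel.  Output labels are
disjoint and renumbered 1..N in raster order.

### Intensity segmentation

An inclusive window `minimum ≤ I ≤ maximum`, no size filtering.  The
printed full range [1, 65535] therefore excludes exactly the zero pixels.
Where a protocol leaves the range unprinted the engine defaults to an Otsu
threshold (lower bound only); a constant plane yields an empty mask.

### Connected components

Foreground connectivity defaults to 8 (diagonal contact within one stained
cell must not split it); labels are assigned 1..N by raster order of each
component's first pixel, so labelling is deterministic.

## Post-processing operators

* **Erosion** — flat structuring element; `disc` (default, diameter = the
  printed kernel size) or `square`.  Pixels outside the image count as
  background.
* **Hole filling** — background components not 4-connected to the border
  become foreground; extensive and idempotent.  On label maps, each
  object's own holes are filled with its label and pixels of other objects
  are never overwritten.
* **Sieve** — retains objects with area strictly greater / strictly less
  than the threshold (the protocol's `greater than: 20 px` on seeds removes
  debris-scale puncta); survivors are relabelled 1..M preserving order.
* **Clump breaking** — splits merged foreground using a second target
  (nuclei or seeds) as separators: every pixel of a mask component that
  contains second-target pixels is assigned the label of the nearest
  second-target *object* (exact Euclidean distance to the object's nearest
  pixel, i.e. a generalised Voronoi partition restricted to the mask), so
  cut lines fall at equal distances between neighbouring nuclei.  Distance
  ties go to the lower label; components without second-target pixels keep
  one fresh label each; no foreground pixel is created or destroyed.
  Object-distance (not centroid-distance) is the default because nuclei are
  extended regions; centroids are recovered as the degenerate case of
  single-pixel seeds.

## Target algebra and nucleation

Protocol 1 derives `GFP negative cells = Cells − GFP cells` by explicit
mask subtraction (the display-window macro formulation of the same
operation is not reproduced).  The GFP-positive target is intersected with
the Cells mask, making the two populations disjoint subsets of the Cells
target by construction.  An optional debris target (intensity segmentation
+ `less_than` sieve) can be subtracted from Cells; it is disabled by
default because its consumer is not specified by the protocols.

**Nucleation rule.**  A cell object survives linking iff some nucleus n
satisfies |n ∩ cell| / |n| ≥ 0.8 — the fraction is measured against the
*nucleus's* pixel count (the machine-readable parameter listing; the
alternative cell-denominator reading is available via
`LinkSpec(denominator="cell")`).  The comparison is exact integer
arithmetic, |n ∩ c| · q ≥ p · |n| with p/q the overlap fraction as a
rational (0.8 → 4/5 via `Fraction.limit_denominator`, deliberately not the
binary float, which is slightly above 4/5 and would misclassify the exact
boundary case).  One qualifying nucleus suffices; `nucleus_of` records the
highest-fraction match, ties to the lower nucleus id.  Survival is decided
by the rule alone — this keeps linking monotone in the overlap fraction; at
the protocol's 0.8 a nucleus can qualify for at most one (disjoint) cell,
so each nucleus nucleates at most one object in practice.

## Measurement

Per object: integer pixel area (µm² added when a pixel size is configured),
centroid, and shape.  "Shape" is reported as the form factor 4πA/P² (1 for
an ideal disc), with eccentricity and solidity as extras.  The perimeter P
is the 4-direction Crofton estimate, whose bias for cell-sized digital
objects stays within ~±20% (a digital disc of radius 20 gives 0.97); the
form factor is meaningful for objects of tens of pixels and above and is
not clamped.  CSV column order is fixed
(`field_id, population, object_id, nucleus_id, area, centroid_x,
centroid_y, form_factor, eccentricity, solidity[, area_um2]`).

## Protocol engine

Both protocols are deterministic operator chains (there is no random state
anywhere in the pipeline, so reruns are bit-identical).  The printed
parameters ship as preset defaults: seed kernel 15 / sensitivity 50 /
erosion 16 / sieve > 20 px; nuclei minimum area 600 px² / sensitivity 15;
overlap 80%.  Parameters the protocols leave unprinted required defaults:

| parameter | default | rationale |
|---|---|---|
| cell-target sieve `less_than` | 15000 px² | ≈3 cell areas at 20×; removes confluent sheets |
| cell-target sieve `greater_than` | 100 px² | well below a nucleus; removes speckle |
| cell-target erosion kernel | 3 px | minimal boundary smoothing |
| intensity range | Otsu lower bound | unprinted ranges are instrument-specific |
| Protocol 2 seed/nuclei numbers | Protocol 1 values | Protocol 2 prints none of its own |

All are overridable via the YAML config (`ProtocolConfig.from_yaml`), which
also carries the channel map, connectivity, overlap fraction/denominator
and debris policy.  Runs abort with a configuration error when a required
channel role is missing; the engine re-asserts the nucleation and
partition invariants on every run and raises if they fail.

## Synthetic fields

The generator emulates one 20× chip field: elliptical nuclei (radii
15–18 px → areas ≈ 700–1000 px², consistent with the 600 px² minimum
target area; eccentricity ≤ 0.3), cytoplasm at 1.55× the nucleus radius,
tag channels lighting the tagged subset's full cell footprint, trapezoidal
post regions (base 100 px, spacing 100 px, emulating the 100 µm PDMS posts)
zeroed in every channel, and two-component noise: Poisson shot noise on the
expected signal plus Gaussian read noise (σ = 2 counts).  The
signal-to-noise ratio is defined as

    snr = (peak nucleus intensity − background mean) / background std,
    background std = sqrt(background_level + read_noise²)

with `background_level` = 9 counts, so at the default snr = 10 the nucleus
peak-to-background ratio is ≈5 — typical of DAPI staining and comfortably
above the seed detector's ratio-2 criterion.  Placement is dart-throwing
with cytoplasm-clearance spacing; with probability `clump_probability` a
cell is instead placed touching a chosen neighbour at centre distance
1.25×(r₁+r₂), which merges the two cytoplasms into one clump while keeping
the ground-truth nuclei disjoint (~8 px gap).  If a clump placement is
geometrically impossible the cell falls back to free placement rather than
deadlocking.  Class labels (gfp/rfp/untagged) are a seeded permutation with
deterministic counts floor(n·fraction + 0.5).  A single `numpy` Generator
seeded from `rng_seed` drives everything; fields are bit-identical under a
fixed seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: point-spread blur and channel bleed-through,
uneven illumination, sprouting/elongated morphologies, out-of-focus debris,
intensity heterogeneity within a population, and z-projection artefacts.
Recovery scores on these fields certify the pipeline's logic (splitting,
classification, linking, counting), not robustness to real-microscope
artefacts, which the protocol's interactive parameter adaptation addresses
in practice.

Scoring against truth matches each detected object to the truth cell whose
region contains the detected nucleus's centroid, resolves candidates
one-to-one greedily by pixel overlap, and reports per class: precision,
recall, F1, absolute count error and total-area ratio.  With zero
detections precision is reported as 0 and flagged degenerate.

## Problem sizes used by the verification scripts

The acceptance script and the heavier tests run 20 seeded 512×512 fields
per protocol (30 cells, 40% GFP; or 10+10 GFP/RFP; snr 10, 20% clumps) —
about 2 s per field — plus 200 random ≤32×32 instances per operator for the
brute-force oracle comparisons and a 10-seed × 3-snr sweep on 256×256
fields for the difficulty monotonicity check.  These sizes give stable
aggregate statistics (mean F1, median count error) while keeping a full run
in the minutes range on one CPU.

## Known limitations

* The vendor semantics of "sensitivity" for the original object/nuclear
  segmenters are not documented; the mappings above are declared
  conventions exposing one monotone knob each, not reconstructions.
* Whether the rounded/octagonal nuclear shape constraint is a hard prior or
  a rendering artefact of the original software is unknowable from its
  description; the opening-based prior here is deliberately mild.
* The sieve direction ("removes objects larger or smaller than a
  threshold") is read as *retain strictly greater / strictly less*; both
  directions are expressible in config.
* No flat-field correction, registration, stitching, z-stacks, time-lapse
  tracking, or learned segmentation.
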