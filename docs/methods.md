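# Methods

This note records the model behind each pipeline stage, the parameters
that matter, what the simulator does and does not emulate, and the design
choices made where the procedure left room.

## Image model and coordinate conventions

Frames are 2-D arrays of camera counts (ADU), indexed `(row, col)` with
row 0 at the top, 0-based. Molecules lie along the flow axis, i.e. the
column (horizontal) axis; the transverse intensity profile of a stained
molecule is a narrow peak that falls off rapidly with row distance from
the centerline. All geometry is integer-pixel; there is no sub-pixel
centerline refinement and no rotation or scale term in the inter-frame
registration (the acquisition stage translates only).

## Skeletonization

A pixel is skeletal when it is a vertical local maximum and its intensity
drops by more than `delta_f` over two pixels both upward and downward. The
four inequalities are evaluated on the 5-pixel vertical neighbourhood
only; the two rows nearest each horizontal border are never candidates
because that neighbourhood is undefined there, and frames shorter than 5
rows are rejected outright.

* `delta_f` (ADU). The expected two-pixel transverse falloff. Default is
  adaptive: 3x the robust noise estimate of the frame
  (1.4826 x median absolute deviation), floored at 1 ADU so a constant
  frame still has a positive threshold. An absolute value can be set in
  the configuration when the acquisition's contrast is known. The adaptive
  default assumes molecules are sparse enough that the frame median
  reflects background.
* `min_span_cols` (default 3). Connected components of skeletal pixels
  spanning fewer columns are discarded as shot-noise specks; a genuine
  fragment at 100 nm/pixel is always wider.
* `connectivity` (default 8) for component labelling (scipy.ndimage).

Components can be locally more than one pixel wide, so each is reduced to
the shortest path between its end points. End points are the brightest
pixel in the component's extreme columns — cut-end coil relaxation makes
fragment ends bright, which is what makes this localization reliable —
with ties broken toward the smaller row. The path search allows
8-neighbour moves whose column strictly increases toward the right end
point, weighted by Euclidean step length (1 or sqrt 2); this guarantees
exactly one pixel per column and makes the thinning idempotent. Equal-cost
ties prefer the smaller (row, col) predecessor so identical inputs always
give identical skeletons. Intensity-weighted edges were considered and
rejected: geometric length is the minimal assumption, and on ridge-shaped
components the two agree wherever it matters. A component whose end
points cannot be joined by column-monotone moves is malformed (e.g. two
ridges glued by a diagonal touch); it is dropped with a warning rather
than aborting the frame.

## Tiling

Landmarks are both end points of every skeletal segment in the two frames
of a pair. For each integer translation in a window centred on the
nominal advance `(0, (1 - overlap) * width)` — half-widths 5 rows and 10 %
of the frame width in columns by default — landmarks are matched one-to-one
greedily in ascending distance within `match_tol_px` (default 2). The
translation with the most matches wins; ties break by smaller residual
sum, then lexicographically. Both end points are used (not only left or
only right) because either may fall in the overlap region.

The estimated translation maps the later frame's coordinates into the
earlier frame's system, so cumulative per-frame offsets are plain prefix
sums and a pixel of frame *k* lives at `pixel + offset[k]` in channel
coordinates. No mosaic image is materialized at any point; all
channel-level reasoning is on shifted coordinates.

If fewer than `min_matches` (default 3) landmarks agree, the nominal
advance is used and the boundary is flagged as a fallback. A fallback
boundary is distrusted for grouping *unless* a duplicate observation —
the same fragment skeletonized in both frames of the pair, with centerline
rows agreeing within the match tolerance over shared columns — confirms
the nominal advance. Any molecule that actually crosses a seam produces
such a duplicate, so an unconfirmed fallback boundary can only separate
segments that no evidence connects; distrusting it unconditionally was
tried first and needlessly split multi-frame molecules whenever an
overlap region happened to contain no fragment end points.

Duplicate observations from the ~25 % overlap are merged after the shift
into channel coordinates: segments from adjacent frames whose column
intervals intersect and whose rows agree are stitched per column,
preferring the larger-span instance where both cover a column. When one
instance contains the other this reduces to keeping the larger; when both
are truncated at their respective frame borders (a fragment longer than
the non-overlapping frame width) the stitch recovers the full extent,
which a keep-the-larger rule alone would undersize.

## Grouping

Candidate links are ordered pairs (l, r) with r strictly to the right
(at least a one-column gap — overlapping fragments cannot be consecutive
pieces of one molecule), facing end points within `max_gap_px` and
fitted orientations within `max_angle_deg`. The working thresholds are
9 px and 15 degrees at 100 nm/pixel. Orientation is the least-squares
line through the segment's pixels, in (-90, 90] degrees relative to the
flow axis; a single-pixel segment is defined as 0 degrees. The score is

    gap / max_gap_px + angle_weight * |d_angle| / max_angle_deg

with `angle_weight = 1` (both criteria equally weighted after
normalization; the procedure specifies the criteria but not a combined
metric). Lower is better; ties prefer smaller gap, then smaller angle
difference, then smaller left-end column — a fully deterministic order.

Linking iterates: every round links all pairs in which each side is the
other's current best valid partner, removes those ports, and repeats
until no mutual-best pair remains; maximal chains become molecule groups
and leftover segments become singletons. Because mutual-best pairs in one
round are mutually disjoint, batch linking equals one-at-a-time linking;
the test suite checks this against a brute-force one-at-a-time oracle on
random instances of up to 6 segments. Links crossing a distrusted frame
boundary are forbidden outright.

Small fragments that "float" away from the deposition axis under high
restriction density are not recovered; that ambiguity belongs to
downstream map-level filters, not the image processor.

## Sizing

The integration mask covers rows r-2..r+2 of each skeletal pixel (5 x
span pixels for an interior fragment), clipped at frame borders.
Background is estimated per frame as the median intensity outside all
masks dilated by 2 px, and each mask pixel contributes
`max(I - background, 0)`; without background correction the conversion
factor would depend on mask area rather than DNA mass alone. Masks that
span several frames are integrated exactly once: each channel column is
owned by a single frame, with ownership switching at the midpoint of each
overlap so integrated pixels stay away from frame edges.

Standards are recognized among the groups by fragment count and by
fluorescence fractions matching the standard's size fractions within a
relative tolerance (`standards_rel_tol`, default 0.2) per fragment, in
given or reversed order since molecules deposit in either orientation.
Per standard molecule the conversion factor is total known kb over total
integrated fluorescence — equivalent to a fluorescence-weighted mean of
per-fragment ratios — and the channel's C_kb is the median across
standard molecules, robust to a partially corrupted standard. Standards
are excluded from the genomic Rmap output and counted separately. A
channel with no identified standard requires an explicit `c_kb_override`
in the configuration; sizing then proceeds identically.

Flags (`frame_boundary`, `distractor_overlap` when a fragment's mask
intersects another group's mask, `near_bright_spot` when any mask pixel
exceeds 3x the group's median skeletal intensity) annotate fragments but
never remove them; filtering on flags is a downstream decision.

## Simulator

The simulator renders what the detector assumes: molecules as horizontal
ridges with a discrete Gaussian transverse profile (sigma
`psf_sigma_px`), gaps of `gap_px` columns at cut sites, end columns
brightened by `cut_end_boost` with total intensity conserved, a constant
background with additive Gaussian read noise, co-deposited lambda
standards, and frames advanced by `(1 - overlap_frac) * width` columns so
noiseless overlap regions are pixel-identical. Every fragment's total
rendered intensity before noise is exactly `adu_per_kb * size_kb`, which
is what makes sizing checkable against ground truth. Defaults and why:

* `frame_shape` (1040, 1392) at `pixel_scale_nm` 100 — a ~140 um
  horizontal span per frame, the standard acquisition geometry.
* `overlap_frac` 0.25 — the engineered frame overlap.
* `kb_per_px` 0.30 — DNA contour per pixel. B-DNA is 0.34 nm/bp; at
  ~85 % surface stretch one 100-nm pixel holds ~350 bp, rounded to
  0.30 kb to stay conservative. (The parameter exists because fragment
  sizes in kb must become pixel lengths.)
* `adu_per_kb` 3000 — sets ridge contrast. With ~900 ADU per column
  spread over the transverse profile the peak sits ~370 ADU above
  background, i.e. peak SNR ~35 against the default read noise, modelling
  the high contrast of intercalator-stained DNA on a dark field. At
  marginal SNR (~10) the falloff inequalities intermittently fail at
  single columns and fragments split; bright staining is the regime the
  detector is built for.
* `psf_sigma_px` 0.8 — transverse profile width (FWHM ~190 nm), chosen
  jointly with the fixed +/-2-pixel mask half-width so the mask captures
  >= 99.6 % of a column's light at any sub-pixel centerline phase; at
  sigma 1.0 the worst phase loses ~1.9 %, violating the 1 % noiseless
  conservation the generator promises. Mask width and optics are
  co-designed in the real instrument too.
* `background_adu` 100, `noise_sigma_adu` 10 — read-noise-dominated
  camera model (Gaussian on constant background; no Poisson shot noise,
  no photobleaching, no surface inhomogeneity).
* `molecule_density` 2.0 per frame, `standards_per_channel` 2,
  `size_range_kb` (30, 300), `cut_rate_per_kb` 0.02 (mean fragment
  ~50 kb), `gap_px` 3, `cut_end_boost` 1.8 (the coil-relaxation
  brightening magnitude is not well quantified; it is exposed as a
  parameter).
* `min_row_spacing_px` 15 between molecule baselines, with centerline
  perturbation amplitude 2 px over a 400-px wavelength (slope well under
  the 15-degree grouping limit), so defaults cannot group across
  molecules while orientation fitting is still exercised.
* `confuser_mode` adds bright 2-px speckles one row off a few genomic
  centerlines (inside the integration mask, close enough that the
  skeleton stays connected through the brightened jog) and one crossing
  ridge at ~12 degrees, to exercise flagging. Recovery of crossing
  molecules themselves is not claimed.

What passing on synthetic channels does *not* show: robustness to
photobleaching gradients, shot-noise statistics, surface or illumination
inhomogeneity, stage jitter beyond integer translation, or densely
crossing molecules. The simulator shares the detector's geometric
assumptions, so these tests validate the algorithms, not the microscope.

## Problem sizes used in the test suite

Unit tests run on frames of a few hundred pixels; the parameter-recovery
test processes one full-size channel (10 frames of 1040 x 1392, 22
molecules, read noise at a tenth of background), which covers the
realistic regime while keeping the suite fast. Oracle-equivalence tests
compare against brute-force implementations on hundreds of random
instances small enough to enumerate exhaustively.

## Known limitations

* Skeletonization is strictly column-axis; platforms presenting
  molecules in other orientations would need the inequalities evaluated
  perpendicular to their dominant direction.
* Integer-pixel registration only; sub-pixel stage drift shows up as
  +/-1 px landmark jitter, absorbed by the match tolerance.
* A detection break at a single column is indistinguishable from a true
  cut site; at realistic contrast this is rare, but it is the dominant
  residual error mode at low SNR.
* Rmap assembly, alignment and map-level filtering of flagged fragments
  are out of scope; the Rmap TSV with flags is the hand-off point.
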