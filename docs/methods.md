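# Methods

## Overview

`ovotrace` analyses dark-field time-lapse image sequences of aquatic
embryos developing inside egg capsules. Each embryo is recorded on a
repeating schedule (e.g. 600 frames at 20 fps, repeated hourly); the
package turns those recordings into morphological traits (area, shape,
position), behavioural traits (centroid movement), spectral "proxy"
traits (blockwise frequency-band energies), a cardiac-rate time series
with a fitted ontogeny model, and per-embryo lethal end points
aggregated into cohort survival curves.

## Egg localisation

The egg capsule is static while the embryo moves inside it. Two maps are
combined to find it: the max-projection over all frames (bright
structures — the capsule ring and every position the embryo visited) and
the temporal variance map (where the embryo moved). Both are min-max
normalised and merged by elementwise maximum. The lowest threshold of a
3-class Otsu separates background from all bright structure (the ring is
dimmer than the embryo, so a 2-class threshold would discard it); holes
are filled — a closed capsule ring becomes a full disc — and an ellipse
is fitted to the largest component from its second moments, inflated by
5% as a safety margin and clipped to the frame. A sequence with no
contrast above background raises an egg-not-found error so the embryo
can be flagged for a manual ROI override (CSV file, one ellipse per
embryo id).

## Embryo segmentation

Within the egg ROI, each frame is median-filtered (3x3), thresholded by
Otsu's method on ROI pixels only (dark-field histograms are strongly
bimodal, and a data-driven threshold makes segmentation invariant to
global affine intensity rescaling), cleaned with one round of binary
opening, and the largest connected component above a floor of 0.1% of
the ROI area is taken as the embryo. Ties go to the component nearest
the ROI centre. Area is computed by the polygon (Green's theorem)
convention on the traced 0.5-level boundary — the same convention used
when outlines are drawn by hand — so automated and manual areas are
directly comparable; centroid, bounding box, solidity and a
boundary-touch flag come from region properties. Frames with no
qualifying component soft-fail to `valid=False` with NaN measures, so
partial sequences keep aligned time axes.

## Blockwise signals and spectra

The ROI bounding box is tiled by L x L grids at levels 1, 2, 4, 8, 16;
each block's mean intensity over pixels inside the ROI ellipse, per
frame, is one signal. Grid boundaries at level L are `floor(i*side/L)`,
which nest exactly along the 1-2-4-16 chain, so the pixel-count-weighted
mean of a block's four children always reproduces the parent — a cheap
internal consistency check that holds on every frame. Grids are anchored
to the static egg ROI, not the moving embryo: stable block identity is
what makes per-block frequency analysis meaningful.

Power spectral densities use Welch's method with Hann window, segment
length `min(256, N)`, 50% overlap, constant detrend, one-sided density
normalisation — the standard defaults of the underlying estimator. At
20 fps / 600 frames this gives a bin width of ~0.078 Hz, ample to
resolve cardiac bands around 1.5-3.5 Hz. NaN gaps (failed frames) up to
5 frames are linearly interpolated; longer gaps mark that block's
spectrum unavailable, which propagates as NaN traits rather than
exceptions.

Band energies integrate the PSD over contiguous bands — by default
0.5 Hz bins from 0 to Nyquist — as differences of one cumulative
trapezoid integral, so refining a band partition never changes the
total. "Total energy" (the sum over all bands) is the holistic activity
proxy: it reflects grey-level fluctuation at all temporal frequencies,
cardiac and behavioural alike.

The per-recording energy traits are computed from the level-4 grid
(summed over its 16 blocks). The whole-ROI level-1 mean is nearly
invariant to a constant-brightness embryo moving inside the ROI, so it
cannot see movement ceasing; level 4 is coarse enough to be robust yet
fine enough that both cardiac intensity fluctuation and gross movement
register.

## Cardiac-rate identification

The heart occupies a small, moving part of the embryo and is often
obscured, so no single block is trusted. Every available block spectrum
is searched in a configurable physiological band (default 0.5-5 Hz,
covering both a ~1.5 Hz snail heart and a ~3.5 Hz amphipod heart while
excluding centroid-drift and Nyquist-adjacent noise). A block qualifies
when its in-band peak is at least 3x the in-band median PSD (quality
`1 - median/peak >= 2/3`), and — one further guard — when the peak is
not sitting on the first or last in-band frequency bin: a maximum at the
band boundary is out-of-band power (broadband movement drift from below,
noise from above) truncated by the band, not a genuine spectral peak.
Without this guard, drift power pooled at the lowest in-band bin across
many blocks can outvote the heart blocks. The reported estimate is the
power-weighted median of the qualifying blocks' peak frequencies; when
no block qualifies the estimate is NaN (heart not visible), never a
clipped boundary value.

Ontogeny models per embryo: ordinary least squares of frequency against
hours (linear kind), or a continuous single-breakpoint piecewise-linear
model (segmented kind) fitted with the hinge basis
`b0 + b1*(t-bp) + b2*max(0, t-bp)` over an exhaustive grid of interior
observed timepoints. The exhaustive search is deterministic, is its own
brute-force oracle, and — because the hinge basis nests the straight
line — the segmented fit's residual sum of squares never exceeds the
linear fit's. Linear fits need >= 5 finite estimates, segmented >= 7;
fewer yields an undefined model with a reason code. Spectra are computed
on full recordings with no excision of cardiac pauses (diapause): the
method is frequency-domain, not beat-timing.

## Lethal end points and survival

Two stage-appropriate signatures:

* **Osmotic failure** (early stages, before heart function): area series
  smoothed by rolling median (window 3); a lethal peak is a local
  maximum at least `1 + delta` (default 1.3x) times the pre-peak
  baseline median, followed by a sustained decline that returns to
  baseline. Monotone healthy growth never qualifies. Death time is the
  peak time.
* **Activity cessation** (later stages): baseline = median in-band
  energy of the first `k = 6` recordings; death is the first recording
  at which the energy stays below `theta = 0.25` of baseline for
  `m = 3` consecutive recordings. Persistence rejects transient dips
  (diapause-like pauses). Raising `theta` can only make calls earlier.

Stage routing: the earliest stage (E3) uses the area peak with the
energy drop as a fallback (a combination of the two); later stages (E7,
E9, E11) use the energy drop. Both stage label sets seen in practice
(E9 and E11 naming for the late stage) are accepted. Death time is
recorded as event onset at the recording interval's resolution.

Cohort survival is the simple empirical proportion (all embryos share
the observation window; censored embryos leave the risk set at last
observation and never count as deaths). The curve is a left-continuous
step function, so an LT percentile is the grid time at which survival
first reaches `1 - p/100` — a cohort dying entirely at 10 h has
LT50 = 10 h exactly. LT25 <= LT50 <= LT75 whenever all are defined.

## Synthetic generator

The generator renders what the analysis consumes: a dark background
(~200 grey levels), a bright static capsule ring (~1200), a growing
bright embryo ellipse (~3000; the >8-bit dynamic range is deliberate),
and a small heart disc whose intensity oscillates sinusoidally at the
set cardiac frequency. The heart is additive intensity, not shape
deformation — the spectral method reads intensity fluctuation, so a
pulsing brightness exercises it fully. The embryo orbits the capsule
centre slowly (2 deg/s) and random-walks 0.25 px/frame, confined to the
capsule interior; Gaussian read noise (sigma = 30) is added per pixel.
Defaults are desk-scale study conditions: 160x160 px frames (the
spectral and segmentation behaviour under test is resolution-free, and
full-resolution rendering adds nothing but time), 600 frames at 20 fps
hourly for 25 recordings, heart at 1.5 Hz; the `orchestia` preset uses
2100 frames at 38 fps, 24 recordings, 3.5 Hz.

Death modes mirror the two detection signatures: *osmotic* — area
spikes by 1.6x for two recordings then settles at 60% of the pre-death
area, with all periodic activity (heart, movement) silenced from the
event onward; *cardiac cessation* — area freezes and all periodic
activity stops. Every stochastic element (centroid path, instantaneous
frequency, analytic area, alive flag) is emitted as ground truth; the
same spec and seed give bit-identical frames.

A trait-level channel (`simulate_trait_series`) emits per-recording
area/energy/movement series straight from the same growth and death
model, with multiplicative noise (1% on area, 20% on energy; dead
energy floor at 2% of baseline). It exists for cohort-scale studies —
e.g. 60-embryo survival curves — where rendering video per embryo adds
cost but no information about the detectors under test.

What the generator does **not** emulate: optical point-spread and
defocus, shape deformation of the beating heart, developmental stage
transitions, multi-embryo wells, illumination drift, and capsule
movement. Passing tests therefore demonstrate correctness of the
measurement chain under the stated image-formation model, not
performance on any particular real acquisition.

## Numerical choices and edge cases

* Pixel coordinates are 0-based, row-major, origin top-left; areas in
  px^2 and, when a um/px scale is set, um^2 via scale^2.
* Timepoint counts are always explicit in configuration, never inferred
  from durations (inclusive vs exclusive hour-counting conventions both
  occur in real schedules).
* Missing or failed frames become NaN rows; time axes are never
  compacted.
* Welch spectra need >= 8 finite samples; shorter or irreparably gapped
  signals yield an unavailability marker, not an exception.
* Equal-size segmentation components tie-break to the ROI centre;
  all-constant ROIs soft-fail.
* The dataset container round-trips bit-exactly (HDF5 via h5py; one
  file per embryo with /traits, /spectra, /cardiac, /endpoints groups);
  files with an unknown layout version raise an explicit migration
  error rather than misreading.
* Problem sizes in the validation suite (e.g. 10-64 frames per recording
  for cohort studies, 50-60 embryo cohorts, 20 replicates per
  frequency-recovery cell) are chosen so the whole suite runs on one CPU
  in minutes while keeping every estimate's sampling error far below the
  tolerance it is tested against.

## Known limitations

* Segmentation assumes one embryo per well and a bright-on-dark scene;
  there is no multi-embryo tracking or stage classification.
* The cardiac identifier reports a single dominant frequency per
  recording; arrhythmia and beat-to-beat statistics are out of scope.
* "Movement" is gross path length of the centroid within a recording,
  not net displacement; with a noisy centroid it is biased upward, which
  matters when comparing against trackers that report net motion.
* Survival curves use the shared-window empirical proportion, not
  Kaplan-Meier weighting; with staggered entry or heavy interval
  censoring a proper survival model should be used instead.
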