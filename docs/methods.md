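# Methods

This note documents the models, parameter choices and numerical decisions
behind `linespark`, and what the synthetic benchmarks do and do not
demonstrate about real recordings.

## The detection model

A line scan is a grid of raw fluorescence `I(x, t)` (rows = space, columns
= time; physical coordinates are pixel centres, `(i + 0.5)·pixel_size`).
Detection assumes sparks are *local, transient elevations over a slowly
varying baseline*; every stage follows from that premise.

**Smoothing.** A separable boxcar of width `space_cutoff × time_cutoff`
(defaults 3 × 3, odd, reflection at edges). A boxcar was chosen over
median or Savitzky–Golay smoothing because it is linear (preserving the
later brute-force testability of every stage), parameter-free beyond its
width, and adequate for shot-noise suppression at these SNRs. It does
correlate neighbouring pixels, which matters below.

**Running-baseline normalization.** Each pixel is divided by the mean of
its temporal neighbours within `half_window` lines on each side, *centre
excluded* so an event does not suppress its own normalization; edge
columns use the available one-sided neighbours so the output keeps full
size. The result is an F/F₀ image with grand mean ≈ 1. The grand mean
carries a small positive bias of order `(relative noise)² / (2·half_window)`
(Jensen's inequality on the reciprocal of the window mean); at realistic
noise (≤ 20% relative SD) this stays well below 0.01. Non-positive pixels
are floored at 1e-6 with a warning so the denominator cannot vanish.

The window must be **long relative to the events being detected**: a
window comparable to the event duration tracks the event itself and both
suppresses the apparent amplitude and distorts the decay. For the
simulated kinetics (~100 ms from onset to near-baseline at 1.89 ms/line,
i.e. ~55 lines) the analyses in the tests and the acceptance script use
`half_window = 200` lines (±378 ms), which bounds the amplitude bias by
roughly `(event integral)/(2·half_window·line_period)` ≈ 5%. The library
default remains 5 lines, appropriate when each "line" already aggregates
a longer sampling interval; it is a user-set parameter precisely because
the right value is a property of the recording.

**Thresholding.** The global SD σ is computed once from the whole
normalized image, and a pixel is marked iff `value − 1 > n·σ`. The
criterion is a *deviation above the normalized mean of 1*: since the
normalized image is centred on 1, a bare `value > n·σ` cutoff with
n ≤ 1.5 would select essentially every pixel and could not produce the
observed monotone decrease of event counts with n. A constant image has
σ = 0 and yields an empty mask with a warning rather than an error.

**Erosion.** One pass (default) of a 3×3 cross erosion with out-of-grid
neighbours treated as empty, removing isolated threshold crossings.
Erosion acts on the binary mask — the only reading under which it can
suppress salt-and-pepper noise of isolated crossings. Because boxcar
smoothing correlates the noise, single crossings are rarer than
*clusters* of crossings; the calibrated preset below uses two passes.

**Localization.** 8-connected components (sparks run diagonally in (x, t),
so 4-connectivity fragments them) with `area ≥ min_area_px` survive; each
carries its pixel set, convex hull (collinear components fall back to
their extreme points), bounding box, and an intensity-weighted centroid
with weights `max(value − 1, 0)` (unweighted mean if all weights vanish).
Candidates are ordered by earliest time line, then lowest spatial index.

### The calibrated preset

Following the package's own recommendation — tune the detection settings
on a training set with ground truth before analysing data — the preset
used for all simulation-scale analyses was fixed by measuring, on seeded
training scans spanning SNR 2–10 and thresholds 0.5–1.5, the area
distributions of true-spark components versus noise components:

| setting | library default | simulation preset | reason |
|---|---|---|---|
| `half_window` | 5 lines | 200 lines | window ≫ event duration (above) |
| `erosion_iterations` | 1 | 2 | smoothing-correlated speckle forms multi-pixel clusters |
| `min_area_px` | 12 | 50 | largest noise cluster ≈ 16 px after two erosions; smallest true-spark component ≥ 160 px across all conditions |
| `threshold_n` | 0.5 | 0.5 (swept 0.5–1.5) | the conventional working threshold |

The two-decade gap between noise-cluster and spark areas makes the preset
insensitive to the exact `min_area_px` value.

## Morphometry

Each candidate is reduced to two 1-D profiles of the normalized image over
a padded window around its bounding box (defaults: ±10 lines, ±3 rows;
simulation analyses use ±40 lines so the decay limb is long enough for a
stable τ fit). Both profiles are **endpoint-equalized**: the straight line
through the first and last samples is subtracted and the profile
re-anchored at 1, removing residual baseline tilt exactly at the
endpoints.

- **FDHM**: half level `1 + (peak − 1)/2`; the crossings nearest the peak
  on each side are located by linear interpolation between samples.
  A peak at the window edge (no crossing on one side) flags the value as
  missing rather than guessing.
- **τ**: bounded least squares (`scipy.optimize.curve_fit`) of
  `A·e^{−t/τ} + 1` from the peak to the window end, initialized with
  A = peak − 1 and τ = FDHM. Only the decay limb is fitted; the rise is
  not modelled.
- **FWHM**: bounded Gaussian fit `A·e^{−(x−μ)²/2σ²} + 1`, initialized from
  the observed half-width; FWHM = 2√(2 ln 2)·σ·pixel_size.

**Spurious-fit guards**: τ exceeding 10× the profile window, σ exceeding
the window width, non-positive fitted amplitude, or optimiser failure all
clear the corresponding `fit_ok` flag and report NaN. This is the defence
against the classic pathologies of automated spark morphometry —
hundred-micron FWHMs and multi-second decay constants — which are better
reported as unmeasurable than as wild numbers. The descriptor-bounds
filter (`SparkBounds`) removes events with any failed fit, since an
unmeasured descriptor cannot be certified in-bounds; such removals are
counted separately from bound violations. Bounds have no package defaults:
a plausibility box is only meaningful relative to the tissue, indicator
and analysis version that produced the training data.

Amplitude is reported as the peak F/F₀ ratio (≥ 1); the fractional
increase is `amplitude − 1`.

## Oscillation-table curation

Events are triaged by duration into `[0, 4)` s (subcellular sparks),
`[4, 40]` s (oscillations; both boundaries inclusive), and `(40, ∞)` s
(slow drifts); only the middle class is filtered.

All percentile and quartile computations use the linear-interpolation
convention of mainstream statistics software, pinned by brute-force oracle
tests (e.g. values 1…9 give Q1 = 3, Q3 = 7, so the 1.5-fence is (−3, 13);
values 1…100 give an 80th-percentile band of (20.8, 80.2)).

Decisions where the convention was genuinely open:

- **Percentile cutoffs are two-sided and symmetric**: the (100−p)th and
  pth percentiles form the band. A one-sided reading would make the four
  levels behave like upper trims only; the two-sided form treats
  implausibly small and large values alike, matching how the fences and
  the data-mined box work.
- **Fences are symmetric with a single multiplier**: `[Q1 − n·IQR,
  Q3 + n·IQR]`, n ∈ {1.5, 3, 5} (arbitrary n via `fence:custom=<n>`).
- **Joint application**: an event must pass *every* bounded parameter
  (amplitude, duration, rise, decay, area) — the same semantics as the
  data-mined box. This makes strict percentile filters aggressive: with
  five independent parameters a p = 80 band keeps roughly 0.6⁵ ≈ 8% of
  in-distribution events.
- **Comparisons are inclusive** at both ends. A degenerate band (constant
  training column) keeps exactly the training value.
- **Training set** defaults to the labeled true positives when labels
  exist (`--train-on gold`), else the whole table.

The data-mined plausibility box (rise 0.78–30 s, decay 0.78–36.72 s,
amplitude 1.25–3.7 F/F₀, area 6.74–108.5 F·s/F₀, duration 4.7–40 s) ships
as an immutable constant: it encodes histogram-derived limits for
smooth-muscle oscillations and is the reference contamination model for
the synthetic tables.

## Metrics and matching

PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), FDR = FP/(TP+FP) = 1 − PPV.
A zero denominator yields `None`/null, never 0 — 0/0 precision is not 0%
performance. For filters on labeled tables, FN counts the true positives
a filter removed (the detector is presumed exhaustive), so the raw method
has sensitivity 1 and the gold-standard method FDR 0 *structurally*; the
tests assert these as identities, not as empirical findings.

Detections are matched to truth one-to-one greedily in ascending
normalized distance `d = max(|Δx|/tol_x, |Δt|/tol_t)` with `d ≤ 1`
required (defaults tol_x = 2 µm, tol_t = 0.1 s; ties broken by truth then
detection index for determinism). Greedy matching can in principle differ
from optimal assignment, but at realistic spark densities it agrees — the
tests assert agreement with the Hungarian-algorithm optimum on randomized
small instances. The time tolerance also absorbs a systematic offset: the
centre of mass of a rise-then-decay transient sits a few lines *after* the
peak, so centroid times trail truth peak times by O(τ).

## The synthetic generator

Simulated sparks are separable — Gaussian in space (σ = FWHM/2.3548),
linear rise then exponential decay in time — on a baseline with optional
linear drift and additive Gaussian read noise, clipped at zero;
SNR ≡ (amplitude − 1)·baseline/noise_sd. Defaults: 128 px × 10,000 lines
at 0.1 µm and 1.89 ms/line (an 18.9 s scan), baseline 100, drift 5%,
amplitude 2.0 F/F₀, FWHM 2.0 µm, rise 25 ms, τ 25 ms — plausible
smooth-muscle spark values; the rise was set so the analytic FDHM,
rise/2 + τ·ln 2 ≈ 30 ms, lands on a typical measured duration. The
benchmark suite cycles a 3 × 3 grid of SNR ∈ {2, 5, 10} × sparks-per-scan
∈ {0, 2, 5}, with per-scan seeds streamed deterministically from one root
seed; well-separated placement spreads onsets over disjoint time slots
(gaps ≫ 3τ).

Synthetic oscillation tables draw true events uniformly inside the
data-mined box; each contaminant parameter is independently drawn outside
the box with a configurable probability (default: amplitude and duration
each 0.5, other parameters 0). Contaminant durations violate only on the
low side (4.0–4.7 s) so contaminants stay inside the 4–40 s oscillation
class and the curation step, not triage, must handle them. Because some
contaminants violate nothing, a raw pass over a 75/25 table has PPV
exactly 75% — the contamination regime ROI detectors typically produce —
while mild contamination leaves the widest fence equal to the raw method.

**What passing does and does not show.** The simulator emits exactly the
shape family the morphometry fits, so parameter-recovery results are a
*consistency* check of the implementation (detection, profile extraction,
fitting, unit conversion), not evidence about model mismatch on real
sparks, which have diffusive spatial spread, asymmetric rise kinetics,
photobleaching beyond linear drift, and motion artifacts. Likewise the
flat detection performance across thresholds reflects the suite's
fixed-amplitude sparks; real threshold sweeps trade sensitivity against
FDR because real amplitude distributions extend into the noise floor.

## Problem sizes and numerical tolerances

- Oracle equivalence: 100 random grids ≤ 32 × 128, exact to float
  round-off (atol 1e-9/1e-10).
- Closed-form fits: noiseless profiles, 1% relative tolerance.
- Parameter recovery: 40 scans × 5 sparks (200 sparks) at SNR 5,
  128 × 4000 lines, threshold 0.5; observed median relative errors ~4–8%
  against a 15% bound; sensitivity ≥ 0.9 and FDR ≤ 0.1 required.
- Threshold behaviour: 50 scans of 128 × 3000 lines over the full
  condition grid, thresholds {0.5, 0.6, 0.7, 1.0, 1.5}; mask nesting is
  exact, counts and sensitivity monotone, and descriptor medians for
  sparks common to thresholds 0.5/1.0/1.5 shift < 10%.
- End-to-end reproducibility: the CLI pipeline (simulate → detect →
  sweep → evaluate) is byte-identical across reruns with one seed.

## Known limitations

- The normalization window and area criterion must be re-tuned per
  acquisition regime; the shipped preset is calibrated to the simulated
  kinetics, and the defaults to nothing in particular.
- Greedy matching has no guarantee of optimality at high spark density.
- The τ fit ignores the rising phase; strongly overlapping events within
  one candidate bias all descriptors.
- No native microscope-container (LSM/CZI) reading: scans enter as
  single-page TIFFs with JSON calibration sidecars.
- Oscillation curation consumes event tables; it does not re-derive event
  parameters from video.
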