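# Methods

`astromap` implements an event-based analysis of astrocyte Ca²⁺ microdomain
(MD) activity recorded in behaving mice, together with a synthetic-data
generator that reproduces the statistical structure the analysis assumes.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not show about real
recordings.

## Input contract

The analysis consumes the per-event output of an event-based Ca²⁺ detector:
a 2D binary footprint (the event's maximal spatial extent), onset and offset
frames `t0`/`t1`, peak ΔF/F amplitude, and footprint area in µm². Derived
quantities are duration `(t1 − t0)/f` at analysis frame rate `f` (10.3 Hz:
a 30.9-Hz resonant-scanner movie mean-binned by 3) and frequency
(events per second of a behavioral state). Events smaller than 2 µm²
(twice the point-spread function) are filtered out. Detection itself is out
of scope; the detector's footprints and timings are taken as given.

## Behavioral states

Treadmill speed (rotary encoder, wheel radius 7.4 cm, circumference
≈ 46.5 cm) and a binary vibrissa-touch train are sampled on the imaging
clock. Frames with speed above `motion_epsilon` are running; a stationary
gap between two movement epochs is merged into the run bout when strictly
shorter than 1.5 s, otherwise it is rest. Touch onsets during running open a
half-open 1.5-s stimulation window (intersected with run frames); touch
frames at rest are vibrissa exploration. Transitions qualify for
peri-transition analysis only when flanked by stable behavior: at least 3 s
of the pre-state and 6 s of the post-state.

Choices the rules do not pin down, resolved here:

* `motion_epsilon` = 0.5 cm/s separates encoder noise from movement; the
  speed trace is effectively binary so any small positive value behaves
  identically.
* A gap of exactly 1.5 s splits the bout ("less than" merges, so equality
  falls to rest).
* The 1.5-s rules are applied on the analysis frame clock; a 1.5-s window at
  10.3 Hz spans ⌈1.5·10.3⌉ = 16 frames.
* Transitions whose stability windows would extend past the recording edges
  are dropped, not padded.

## Event statistics

Events are assigned to states by their **onset frame** only. Substates take
precedence for the per-event tag, but the rest/run summary rows count events
by base state (an event inside a stimulation window is still run activity),
so the two base rows partition all events; substate rows are overlapping
subsets whose frequency denominator is total substate time. Means are
reported with t-based 95% confidence intervals.

Peri-transition profiles pool event onsets across transitions into 1-s bins
over a −3…+6 s window. Bin frequency is pooled count / (transitions × bin
width). Each bin is tested against the bin containing −1 s: per-transition
counts (frequency) or pooled event values (amplitude, duration, size) with a
Kruskal-Wallis test, Bonferroni-corrected over the non-reference bins. Note
one quantization artifact: at 10.3 Hz a 1-s bin holds 10 or 11 frames, so
frequencies computed against the nominal bin width carry a ≤3% bias; rate
*ratios* should be estimated against actual frame coverage (the calibration
test does).

Distribution fits: amplitude and duration margins use maximum-likelihood
skew-normal fits. Event sizes are heavy-tailed; above a fixed floor
`xmin = 5 µm²` the tail is fit by conditional maximum likelihood under three
families — power law (`α̂ = 1 + n/Σ ln(x/xmin)`), shifted exponential
(`λ̂ = 1/(x̄ − xmin)`), and truncated lognormal (Nelder-Mead on the
conditional likelihood) — and families are compared pairwise with the
normalized log-likelihood-ratio (Vuong) test; the sign prefers a family and
the two-sided normal p-value states whether the preference is significant.
This component is implemented in-package and validated against simulations
with known ground truth (α recovery to ±0.1; lognormal-vs-exponential
discrimination).

The hypothesis-testing protocol mirrors the study design: normality per
group by Shapiro-Wilk below 50 samples and Kolmogorov-Smirnov otherwise
(exactly 50 uses KS), α = 0.05, two-tailed throughout; all-normal groups go
to t-tests or one-way ANOVA with Tukey post hoc, anything else to
Mann-Whitney/Wilcoxon or Kruskal-Wallis with Bonferroni-corrected pairwise
tests. The KS test is applied to standardized samples; with estimated
moments it is conservative, which only makes the nonparametric branch more
likely — the safe direction. Multi-pole (rest-normalized) comparisons divide
each recording's state means by the same recording's rest means, so rest
rows are exactly 1 and between-recording baseline variability cancels.

## Activity heatmaps and the random-placement null

A heatmap sums binarized footprints over a frame subset: an event
contributes 1 to each footprint pixel when its active interval `[t0, t1]`
intersects the subset (onset-only membership is available as a flag).
Normalization divides by minutes used, then by the maximum pixel
(`max_one`); the per-minute step cancels in correlations but is kept for
exported maps.

The null model redistributes the same amount of activity uniformly:
ellipses with areas resampled (with replacement) from the recording's event
areas, uniform orientation, eccentricity uniform in [0, 0.95], centers
uniform over the cell mask, clipped to the mask; placement stops when the
cumulative **clipped** area reaches the real total (the last ellipse may
overshoot by at most one pool area). Whether the original procedure clipped
ellipses or rejected boundary placements is not specified; clipping is used
and the clipped area counts, keeping area accounting exact.

Map similarity is the maximum Pearson correlation over integer translations
(default search radius: a quarter of the grid), computed over the overlap
region with zeros included; translations overlapping less than half the
grid are excluded. The sliding sums are FFT-accelerated and match an
exhaustive per-shift computation to 1e-10 (tested). The reported translation
is the displacement of the second map relative to the first. Between-day
comparisons first align the recordings' binary activity masks (union of
footprints) by the same criterion, then compare heatmaps. Within-day
stability splits a state's frames into k contiguous-in-state-time blocks of
equal length (±1 frame) and correlates their maps pairwise; the
recording-length curve compares initial subsequences of increasing length
against the full-recording map, reported as max-PCC (the original "percent
similarity" unit is not defined; max-PCC × 100 is the assumption made here).

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions:

| parameter | default | anchor |
|---|---|---|
| grid, pixel size | 512 px, 94/512 µm/px | imaging field of view |
| frame rate | 10.3 Hz | temporally binned movie |
| rest / run rate | 0.95 / 3.7 events/s | reported state means |
| amplitude mean | 1.6 ΔF/F | reported mean |
| duration mean | 1.1 s | reported mean |
| size lognormal (µ, σ) | (1.48, 0.9) ln µm² | mean ≈ 6.6 µm² (rest mean size) |
| log-size–duration r | 0.42 | reported Pearson r |
| skew-normal shape | 3 | right-skewed margins; only means are anchored |
| hotspots | 6 bumps, σ = 3 µm, weight 0.7 | produces clear hotspot maps |

The cell mask is a thresholded band-limited Gaussian field under a broad
central envelope (largest connected component, holes filled) — a cloud-like
single territory covering 5–60% of the grid. The hotspot field mixes
isotropic Gaussian bumps (renormalized over the mask so edge clipping does
not shift weights) with a uniform floor.

Event streams: onsets are an inhomogeneous Poisson process (per-frame rates
by behavioral state); centers are drawn from the hotspot field; footprints
are ellipses of the drawn area (axis ratio uniform in [0.3, 1]) clipped to
the mask, and the clipped pixel count defines the recorded area. Sizes and
durations are coupled through a Gaussian copula. Because duration is
skew-normal rather than normal, a latent correlation ρ equal to the target r
would under-deliver; the generator sets ρ = r / c where
c = corr(Z, F⁻¹(Φ(Z))) is computed by quadrature (c ≈ 0.98 at the default
margin), so the *observed* Pearson correlation between ln(size) and duration
lands on the target. Durations are quantized to frames (minimum 2 frames,
the detector's resolution floor); amplitude is an independent skew-normal
resampled to positivity. At n = 5×10⁴ the generated means land within 2% of
their targets and r within ±0.03, verified in the test suite.

Behavior traces alternate exponential-length rest/run bouts (means 12 s and
9 s, minimum 2 s) with a trapezoidal speed profile (1-s ramps, 15 cm/s
plateau — the profile shape is unconstrained by the source rules); touches
fire at every pole-spacing of cumulative distance, so only while moving.

Puncta stacks place uniform bright disks (areas uniform in a configured
range, default 0.1–0.5 µm²), each confined to one optical section
(sub-micrometer objects at 0.7-µm section spacing), disjoint in x-y with a
margin, at least 2 sections from the axial stack edges (boundary sections
only partially sample real objects, and reflective smoothing boundaries
would otherwise distort them), plus Gaussian noise.

## Puncta detection

Stacks are converted to 8 bits with a **fixed** intensity mapping (the
brightness/contrast setting of the workflow, established once and held
constant across compared groups), smoothed with an isotropic 1-voxel 3D
Gaussian, thresholded at a fraction of the 8-bit range, and counted as
per-section 8-connected components with 2D area inside the size gate
(default 0.1–0.5 µm²). Density is count / (image area × 0.7 µm × number of
sections). The threshold has **no default**: it is an empirical parameter of
the procedure.

Two consequences of the 3D smoothing matter for validation. First, the
z-kernel leaves a ghost of each punctum in adjacent sections at ≈0.61 of its
smoothed peak, so a usable threshold must sit between ghost and real peaks;
at the validation conditions this is 0.33 of the 8-bit range with the
mapping fixed at (0, 200). Second, thresholding erodes the measured 2D area
by roughly 0.05 µm² relative to the true disk area, so round-trip validation
draws true areas in (0.15, 0.5) µm² and gates measured areas at
(0.06, 0.5) µm². Under these settings count recovery is exact across tested
seeds at peak signal-to-noise ratios from 5 to 20, and density follows
exactly from the count. Objects genuinely spanning several sections would be
counted once per section — a property of the per-section procedure itself,
not a bug.

## What the synthetic data do not show

The generator reproduces marginal distributions, state-dependent rates, a
size-duration copula, and stationary spatial hotspots. It does not model
photobleaching, motion artifacts, detector noise, event-shape irregularity
(real footprints are not ellipses), within-bout rate dynamics (e.g.,
acceleration-phase transients), day-to-day remodeling of hotspots, or
between-astrocyte heterogeneity. Passing parameter-recovery and ordering
tests therefore demonstrates that the pipeline measures what it claims on
data with the assumed structure — not that real astrocytes satisfy those
assumptions. Headline values that depend on the original recordings (the
absolute self/random/state/day PCC levels, the 85%-at-20-min similarity) are
reproduced only as orderings and trends, at reduced problem sizes chosen for
desk-scale runs: 64–128-px grids spanning the same 94-µm field of view,
900-s rest recordings for map stability (40 seeds), 400 synthetic
transitions for profile calibration, and 8×256×256 stacks with 20 puncta
for the round trip.
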