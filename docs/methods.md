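# Methods

This note records the models, conventions and numerical choices behind
`calsig`, in the spirit of a methods section: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
establish about real recordings.

## Synthetic transients

### Waveform family

Each cell's calcium signal (in ratio units above its baseline) is built
from **piecewise exponential relaxation**: a schedule of
(start time, target level, time constant) segments evaluated
sequentially, plus raised-cosine spikes. The family was chosen for
differentiability and — above all — parameter identifiability: every
shape parameter a later stage must recover is an explicit knot of the
construction.

Three details matter:

- **Exact peaks.** A rise segment's target is boosted so the trace
  attains the peak amplitude *A* exactly at the nominal peak time, after
  which the decay segment takes over. The rise span is chosen so the
  slopes flanking the peak are of similar magnitude; a cusp with one flat
  flank has no well-defined maximum once any smoothing is applied.
- **Guaranteed half-maximum crossing.** Several observed classes hold a
  plateau *C* above half their peak (*C* > *A*/2), so a monotone decay
  toward *C* would never cross baseline + *A*/2 and the FWHM would be
  undefined. The decay therefore relaxes toward a floor
  min(*C*, 0.35 *A*), crossing the half-maximum at the prescribed FWHM,
  and then relaxes up to the plateau. The transient dip is brief
  (recovery τ = 90 s) and does not change the class read-out.
- **Spiking after re-basing.** Classes defined as
  "peak–baseline–spiking" start their spike train only once the decay has
  genuinely returned toward baseline (start time ≥ peak time +
  4 × FWHM + 300 s), matching the class definition; spike trains are
  periodic with interval *D* and 40 s raised-cosine bumps.

### Population priors

Two kinds of priors exist:

- **Shape priors** (`atp_shape_priors`, `wound_shape_priors`): one
  distribution per secondary class, with amplitudes/plateaus/FWHMs at
  the published per-class scales and timing conventions that satisfy each
  class's defining predicate (slow classes rise with onset ≥ ~3 min;
  rapid classes reach half-peak within ~1 min). Wound priors draw
  amplitudes, FWHMs and plateaus from lognormal fits of the published
  proximal/distal cell-level moments.
- **Primary-class metric priors** (`primary_class_population`): per-cell
  target metrics drawn from the published per-primary-class means with
  cell-level s.d. taken as s.e.m.·√n (n = pooled class count), **capped
  at CV = 1**. The cap keeps the synthetic spread consistent with the
  cell-level CVs printed for the wound protocol (0.4–1.5) and keeps
  waveforms resolvable within the recording (an FWHM longer than the
  initial-response window leaves the peak time unidentifiable; FWHM
  draws are clipped at 8 min for the rapid classes for the same reason).
  Plateaus for the peak–plateau class are drawn as a ratio of the peak
  (mean 0.76, clipped at 0.85) so the population plateau mean is
  preserved under the plateau ≤ peak constraint. Spiking-class pedestals
  are capped below the spike re-basing level so spikes remain
  detectable.

Class mixtures default to the published pooled proportions (ATP) and to
the early-response group fractions of the wound protocol (proximal
10/64/26 % slow / peak–plateau / peak–baseline, distal ≈ 40/1/59 %),
with within-group secondary splits chosen by us.

### Rendering

Cells are soft-edged discs (logistic edge, 1.5 px softness) on a jittered
rectangular packing (default 121 cells in 512×512 px at 0.65 µm/px,
matching a ×20 objective convention; the scratch-wound layout removes a
60 px strip and yields ≈ 253 surviving cells at the default density). The
calcium-increasing channel is linear in the calcium proxy; the decreasing
channel saturates as gain / (1 + x/8), so the green/red ratio is strictly
monotone in calcium and near-affine over the physiological range
(noiseless single-cell renders give ratio–truth correlation ≥ 0.99).
Per-cell dye loading varies lognormally (CV 0.15) — exactly the artifact
ratiometric imaging is meant to cancel. Camera noise is Gaussian read
noise plus a sqrt-intensity shot-noise term. **Not modelled:**
photobleaching, cell motility, the optical PSF, out-of-focus light. A
real recording also has non-disc cell shapes and spatially correlated
background; the 96 %-recall benchmark therefore validates the algorithm's
logic and its default parameterization, not its performance on any
particular microscope.

## Segmentation

"Adaptive-threshold watershed" is implemented as intensity-connected
region growing from the global-maximum seed down to
`roi_threshold_fraction` (0.5) of the seed's own intensity — the
threshold adapts to each cell's brightness — under an 8-connected
topology and a `max_radius_px` (30) constraint; a second region at
`halo_threshold_fraction` (0.3) is zeroed to separate neighbors.
Classical gradient watershed is deliberately not used. Ties for the
maximum break to the lowest (row, column), making extraction
deterministic. Iteration stops at `max_roi_count` or when the residual
maximum falls below `mask_threshold`, so sparse images terminate without
user input. Defaults (blur σ 2 px, mask threshold 0.08,
local-mean window 31 px with fraction 0.8, size gate 50–2000 px) were
calibrated on the synthetic monolayer to exceed 96 % recall; the
local-mean fraction is the load-bearing one — it clears inter-cell
ridges and dim edge remnants that would otherwise seed duplicate ROIs.

## Signature metrics

- **Baseline**: mean of pre-stimulus samples (first 5 % when recording
  starts at the stimulus).
- **Denoising**: samples whose central-difference slope over a 15 s
  window is below 0.01 a.u./s are replaced by the local mean over the
  same window; steep samples pass through, so peaks and spike flanks are
  not broadened. The local mean does clip a sharp peak cusp by a few
  per cent; metrics quoted to better accuracy should be computed on
  noise-free traces directly.
- **Initial peak**: maximum within stimulus → +10 min; a response
  requires A ≥ 0.15 a.u. Peak *time* is read from a 9 s
  uniformly-smoothed copy (the raw argmax of a broad peak jitters with
  residual noise). If the late plateau exceeds the windowed maximum, the
  trace is a slow riser and *has no initial peak* (FWHM 0).
- **FWHM**: first fall below baseline + A/2 after the peak
  (baseline-relative: the standard convention); capped at the recording
  end. Reported in minutes.
- **Plateau**: median of the final third; `has_plateau` additionally
  requires the last 2 min to hold above 0.10 a.u. A dual plateau is
  declared when the largest 4-min step-down in the smoothed post-peak
  trace separates two flat (≤ 0.05 drift) levels ≥ 0.12 apart with the
  lower one still elevated; the step is located as the *last* qualifying
  drop, because the initial decay itself is a large drop.
- **Spikes**: post-peak maxima with prominence ≥ 0.12 and ≥ 60 s
  separation count as spikes only when the trace returns below
  baseline + 0.35·A between them. The re-base fraction of 0.35 (rather
  than a stricter 0.25) allows spiking atop the moderate pedestals these
  recordings show; with 0.25 a spiking class could not simultaneously
  express its published plateau height. Rate = 1/mean interval; zero
  with fewer than two spikes.

## Classification

The tree: no response → 1a; slow onset (latency to half-peak > 2 min) →
1b / 1c / W1 by terminal state; rapid with spiking → 2c (spiking ends,
terminal plateau ≥ 5 min), 3c (stable elevated level just before the
first spike) or 3b; rapid with one discrete extra peak (width-capped, so
broad plateaus do not qualify) → 2b (elevated just before the second
peak) else 3a / W4 by protocol and terminal state; rapid single peak →
2a / 3a (ATP) or 2a / W2 / W3 / W5 (wound) from the post-peak epoch
sequence and the dual-plateau detector. "Rapid" is decided by onset
latency, not peak time, which reconciles late *extracted* peak times
(second peaks in the window) with rapid onsets. Every input maps to
exactly one class; two off-taxonomy shapes are folded into their nearest
class (ATP rapid peak→baseline with nothing after → 3a; wound rapid
peak→straight baseline → W2 with a degenerate plateau). The minimal
terminal-plateau duration separating 2c from 3b is a convention (5 min).
On synthetic data the classifier is exact in the noiseless limit and
≥ 90 % correct at the default noise (σ 0.03 a.u.).

## Spatial statistics

Distances are centroid-to-polyline (declared in output metadata;
nearest-boundary-pixel is a defensible alternative the package does not
use). The nominal split assigns exactly 100 µm to *distal* (proximal is
strictly < 100 µm), while the sweep tests ≤ x vs > x, each convention as
printed at its source. Mann–Whitney uses midranks, exact enumeration for
tie-free samples with n ≤ 12 and the tie-corrected continuity-corrected
normal approximation otherwise; Kruskal–Wallis is tie-corrected with a
χ² reference; Dunn's z-statistics on mean ranks are Bonferroni-adjusted
over the k(k−1)/2 pairs. Degenerate inputs (identical constants) return
p = 1 rather than an error.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
150–360 transients per recovery study, a 121-cell rendered monolayer for
segmentation, 76/178 cells for the wound contrast and 1000 replicates
for the null-calibration check — sizes chosen to match the published
experiments where a size is published and to keep Monte-Carlo error well
inside the stated tolerances elsewhere.

## Known limitations

- The rendered benchmark idealizes cell geometry and noise (see above).
- Population s.d. values for the ATP classes are reconstructed from
  printed s.e.m. values under a pooled-cell-count reading with a CV cap;
  the true cell-level spreads are not published.
- The wound-protocol class mixtures are specified at the
  early-response-group level; the secondary-class splits within groups
  are package choices.
- Classification thresholds (response 0.15, plateau 0.10, rapid latency
  2 min, epoch window 90 s) are calibrated on the synthetic suite; real
  recordings with different dynamic range will need the config block
  re-tuned.
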