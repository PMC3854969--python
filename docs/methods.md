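# Methods

## The biological setting

ARL13B (ARL-13 in *C. elegans*) is a Joubert-syndrome-associated membrane
GTPase confined to an Inversin-like subdomain of the proximal ciliary
membrane (the middle segment, MS), excluded from the ~1 µm transition zone
(TZ) that separates the cilium from the periciliary membrane (PCM) at the
dendritic tip. Compartmental FRAP experiments probe whether the TZ acts as
a diffusion barrier: bleaching one pool and watching whether fluorescence
returns from the reciprocal pool distinguishes an intact barrier
(wild-type-like, slow/no ciliary–PCM exchange) from a compromised one
(mks-5-class mutants, rapid exchange). This package implements the
quantitative machinery of that assay — a stochastic membrane simulator as
the data source, the FRAP ratio statistic and one-phase fit, kymograph
velocimetry for IFT-like particle motion, and the AP-MS filtering rules
used to define the ARL13B protein complex.

## Membrane simulator

**Geometry.** A 1D interval `[0, L_pcm + L_tz + L_ms + L_ds]` in µm, origin
at the proximal PCM boundary, anterograde = increasing coordinate. Defaults:
`L_pcm = 2`, `L_tz = 1` (the observed TZ "gap"), `L_ms = 3` (the proximal
ciliary compartment), `L_ds = 0`. Outer boundaries reflect (sealed dendrite
and ciliary tip); an optional `dendrite_rate` exchanges PCM molecules with
an external fluorescent reservoir and defaults to 0, matching the
observation of essentially no recovery when both pools are quenched.

**Dynamics.** Each molecule takes Gaussian steps of sd `sqrt(2 D dt)`. A
step that would cross a TZ boundary succeeds with probability `p_tz` and is
otherwise specularly reflected about the boundary. Two modes:

- *intact* (`tz_occupancy = False`): molecules never reside inside the TZ
  interval; a successful crossing translates the step across the excluded
  interval. This encodes the wild-type picture in which ARL-13 is absent
  from the TZ membrane.
- *compromised* (`tz_occupancy = True`): the TZ is occupiable and its two
  boundaries act as independent semi-permeable walls; with `p_tz = 1` the
  domain is freely diffusible (the mutant picture).

The microphysics of the barrier is not known; the per-attempt crossing
probability is a model construct, not a measured quantity, and no attempt
is made to map `p_tz` onto the (unknown) in vivo permeability. Likewise
`D` is a free parameter; the default 0.1 µm²/s is a typical lateral
diffusivity for ciliary membrane proteins. All correctness claims are
therefore parameter-recovery and ordering claims (e.g. intact-mode
recovery is at least 4× slower than compromised-mode recovery), not
reproductions of the printed worm half-times.

**Stability.** `sqrt(2 D dt) ≤ L_tz / 2` is enforced so that a single step
practically never spans both TZ walls; the rare double crossing is resolved
sequentially, wall by wall. The default `dt = 0.25 s` satisfies this for
all diffusivities used here.

**Photobleaching** is instantaneous per event (the real 100 µs laser dwell
is far below any `dt` of interest) and stochastic per molecule with
probability `bleach_efficiency` (default 0.95). Fluorescence is binary;
total molecule count is conserved and the fluorescent count is monotone
non-increasing (with `dendrite_rate = 0`).

**Imaging model.** ROI readout = `gain · (fluorescent count in ROI) +
background + N(0, sigma)`, floored at 0. Poisson shot noise is omitted:
the ratio statistic divides it out to first order at the gains used, and
the Gaussian read-noise term dominates the EM-CCD regime being emulated.

**IFT-like transport** (optional): molecules bind trains at rate `k_on`
(within the cilium), ride ballistically at `v_ant`/`v_ret`, release at
rate `k_off` or at the ends of the track, and cross the TZ freely while
bound (active transport across the barrier). The kymograph simulator uses
discrete train injections instead: anterograde particles at the base and
retrograde at the tip, either as a Poisson process (`train_rate`) or with
an exact particle count whose birth times are evenly spaced with ±30%
jitter, so that simultaneous trains never overlap within the
point-spread function — matching the discrete, countable particles the
assay actually measures. Default `v_ant = 0.65 µm/s` (the measured
anterograde speed); no default retrograde speed is claimed.

**Acquisition schedules.** Two presets mirror the published protocols:
intraciliary (post-bleach frames at 1, 15, 30, 60, 120, 180, 240, 360,
480, 600 s) and compartmental (…, 300, 600, 900, 1200 s). The "immediately
post-bleach" frame is encoded at t = 1 s (the first-frame latency is not
stated); both presets include it, since the one-phase fit needs the
post-bleach anchor and the published compartment-FRAP curves show a t0
point. Two pre-bleach frames are used (count not stated; two suffice for
the pre-bleach normalisation).

## The exact-kernel oracle

`expected_trace` computes the noise-free expectation of the stochastic
simulator by iterating the exact one-step transition kernel of the same
step rule on a position grid (bin width ≤ `sqrt(2 D dt) / 2`, walls aligned
to bin edges). The Gaussian proposal is integrated by dense quadrature
(±5 sd, 801 nodes) and the barrier Bernoulli is expanded into weighted
branches, so the kernel involves no sampling and no seed. Bleach events
multiply the fluorescent density in the ROI by `1 − efficiency · overlap`.
The oracle supports pure-diffusion configurations only (directed transport
would require augmenting the state space) and is used to check that
Monte-Carlo ensemble means agree with the expectation within 3 standard
errors at every timepoint across intact, leaky and compromised
configurations.

## FRAP analysis

**Ratio statistic.** `value(t) = [(I_bleached − BG)/(I_reference − BG)] /
R_pre` with `R_pre` the mean pre-bleach ratio and times shifted so the
bleach is t = 0. Background is a single scalar per trace (a dedicated
background ROI in practice). The ratio is invariant to uniform acquisition
photobleaching of both ROIs — the reason the assay uses it.

**Both-pools control.** When PCM and cilium are bleached together no
unbleached reference remains, so the readout is the summed
background-subtracted pool intensity normalised to its pre-bleach mean
(`pool_intensity_curve`). The simulated whole-cell quench covers the
entire domain, including TZ-resident molecules in compromised mode —
otherwise the unbleached TZ pool would masquerade as external recovery.
This control is the sealed-system null: recovery above its post-bleach
floor means signal is arriving from outside the two pools.

**Baseline subtraction** removes the null control's excess over its own
post-bleach floor from a single-pool curve, then re-imposes the pre-bleach
normalisation, mirroring the published correction of single-pool curves
for residual whole-cell recovery.

**One-phase association fit.** `F(t) = plateau − (plateau − f0) e^{−kt}`
on post-bleach points only (whether the original fits included pre-bleach
points is unstated; post-only is adopted). Bounded least squares with
`k ∈ [1e−5, 10] s⁻¹`; initialisation: `f0` = first post-bleach value,
`plateau` = mean of the last two, `k` from a log-linear regression of
`plateau − F`. `t½ = ln 2 / k`; `R² = 1 − SSres/SStot` (defined as 0 for a
perfectly flat curve); the quality gate is exactly `R² > 0.75` with no
epsilon. Non-convergence is flagged, not raised.

**Exchange classification.** `exchanging` requires both single-pool
recoveries to be fast and near-complete (`plateau ≥ 0.8` of pre-bleach,
`t½ ≤ 60 s`) while the null control recovers ≤ 0.1; a recovering null
makes the assessment `indeterminate` with source `external`. The
reciprocal-pool attribution requires the non-bleached pool to decline by
≥ 5% between bleach and the last frame (the published analysis shows this
decline qualitatively; the fractional-drop implementation here is not
calibrated against it). All four thresholds are configurable; the defaults
separate the intact and compromised simulator modes with a wide margin and
are deliberately round numbers between the two regimes.

**Compartment quantification.** Ciliary fraction = `(cilium − bg) /
((cilium − bg) + (pcm − bg))`, each term clamped at ≥ 0. Compartment
length = longest contiguous pixel run at ≥ 50% of the background-subtracted
maximum (FWHM convention; no rule is published) × pixel size. Group
comparisons use one-way ANOVA with Bonferroni-multiplied pairwise p-values
capped at 1; zero-variance identical groups compare at p = 1.

## Kymograph velocimetry

Particles are detected per frame as local maxima above
`median + 5 · MAD` (robust to uniform offsets), sub-pixel refined by
3-point parabolic interpolation; the two outermost pixel columns are
excluded because a truncated PSF biases the parabola. Linking is greedy
nearest-neighbour with `max_jump = 5 px` and a one-frame gap tolerance;
ties break by smallest displacement then leftmost position; tracks shorter
than 4 points are dropped. Velocity is the least-squares slope of position
vs time × pixel size (no pause/run segmentation — single speeds are
reported). Greedy NN linking can swap identities when two tracks cross
symmetrically; the velocimetry validation therefore uses non-crossing
scenarios, and crossing behaviour is tested with asymmetric speeds. The
defaults (`min_track_len = 4`, `max_jump = 5`, `snr = 5`) were chosen for
robustness; the original measurements were made by hand on kymographs, so
automated estimates are validated against simulator ground truth only.

## AP-MS filtering

TAP retention is the conjunction (order-irrelevant) of: identified in ≥ 2
of 3 experiments with ≥ 2 peptides, peptide probability > 80% (strict),
protein probability ≥ 95% (inclusive, "threshold was set to 95%"),
and control-run frequency < 15% ("15% or more" removes — inclusive). The
bait is always retained. The summary table keeps proteins with average
peptide count > 1.5, sorted descending with alphabetical tie-break.

SILAC: a protein qualifies with ≥ 2 peptides quantified in ≥ 2 of 3
replicates; enrichment = `2^(median log2 H/L)` (median across replicates —
the aggregation is unstated; the median is used for outlier robustness) and
is retained at ≥ 2-fold (inclusive). Not-quantified proteins carry an
explicit `nd` marker, distinct from 0 or missing.

Significance A is the robust outlier p-value of a log-ratio: with
percentiles `p15.87, p50, p84.13` of the ratio distribution,
`z = (r − p50)/(p84.13 − p50)` above the median (reflected with the lower
spread below it) and `p = erfc(z/√2)/2`, giving `p = 0.5` at the median
and ≈ 0.1587 one robust-sd above it. The originating quantification
software's definition is adopted; the published analysis does not print
the formula, so exact numeric parity with the original runs cannot be
verified. It is applied one-tailed on the enrichment side;
multiple-testing adjustment is available but off by default.

The synthetic AP-MS generator draws interactor peptide counts as Poisson
variables, contaminant control-run appearances as Bernoulli trials, and
SILAC log2 ratios as the true enrichment plus Gaussian noise. It emulates
count sparsity and contaminant structure but not peptide-level effects
(shared peptides, missing-value mechanisms, intensity-dependent variance),
so passing filters on synthetic data demonstrates rule correctness, not
real-data performance.

## Problem sizes and determinism

All randomness flows from a single integer seed; replicate *i* of an
ensemble uses `seed + i`. Validation runs use 300–5 000 molecules,
`dt = 0.25 s` and 20–40 replicates per configuration — sizes at which the
Monte-Carlo standard errors are a few percent of the signal and the whole
validation suite completes in well under a minute per check. Known
limitations: 1D geometry only (no curvature, no 2D bleach-geometry
corrections), binary photophysics (no blinking, no photoconversion), no
reaction–diffusion decomposition of recovery into binding and diffusion
components, and no decoy-based FDR machinery in the AP-MS stage.
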