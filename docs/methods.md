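# Methods

`ms2burst` quantifies transcriptional bursting from two-channel live-imaging
movies of early embryos: a histone-marker channel for nuclei and an MS2/MCP
channel in which nascent transcription appears as one diffraction-limited
nuclear dot. This note documents the models, the analysis conventions, the
synthetic data used for validation, and the numerical choices that were
genuinely open.

## Signal model

The generator treats each promoter as a two-state telegraph process:

* OFF → ON at rate `k_on` (per minute), ON → OFF at rate `k_off`;
  dwell times are exponential.  Optionally the ON exit proceeds through
  `off_steps` sequential exponential stages (total mean preserved at
  `1/k_off`), giving Erlang ON durations — a multi-step switch-off that
  breaks ON-duration exponentiality while leaving OFF durations
  single-exponential.
* While ON, Pol II initiates as a Poisson process at `r_load` per minute.
* Each nascent transcript contributes `unit_intensity` fluorescence units
  for exactly `dwell` minutes (a boxcar kernel).  A triangular
  elongation ramp would be more literal but does not change what the burst
  caller is sensitive to; the kernel is isolated in one function and
  swappable.
* The sampled trace adds Gaussian noise (`noise_sd`), clipped at zero —
  background-subtracted photon noise without a camera model.

Switching is simulated event-by-event in continuous time (Gillespie-style)
and only *sampled* on the frame grid, so dwell-time distributions are exact
rather than Bernoulli approximations.

Rendered movies place non-overlapping disk nuclei (random sequential
placement; an error is raised if a disk cannot be placed in 1,000 attempts)
that drift by per-frame Gaussian steps.  Steps that would bring two disks
into contact are rejected for the nuclei involved — interphase nuclei
exclude each other, and uncontrolled overlap would test the segmentation on
geometry the real tissue never produces.  The histone channel renders each
disk with a radial intensity profile, a per-nucleus gain, and a small
saturated chromocenter-like speckle (so the bright-pixel suppression step of
segmentation method 2 has something to do).  The MS2 channel renders, per
nucleus, an isotropic 2-D Gaussian dot (sigma `psf_sigma`, default 1.5 px)
whose *integrated* intensity equals the true trajectory value, placed at a
fixed random offset inside the nucleus on one "home" z-plane, with
Gaussian-attenuated copies on neighboring planes so brightest-z selection is
exercised.  Movies are 16-bit; three z-planes are rendered by default —
enough to exercise 3-D localization without inflating memory.

What the generator does *not* emulate: mitosis and nuclear divisions,
deformable nuclear shapes, chromatic or stage drift, photobleaching, and a
realistic PSF/camera chain.  Passing the round-trip tests therefore shows
the analysis is internally consistent and accurate on blob-like nuclei with
Gaussian dots; it does not certify performance on crowded or dividing
tissue.

### Promoter-variant presets

`variant_presets` encodes six parameter sets (WT, mTATA, mInr, mMTE, mDPE,
Zelda) whose *ordinal* relations follow the qualitative biology: the TATA
mutant lowers loading rate (amplitude) and activation rate (frequency); the
Inr/MTE/DPE mutants lower the activation rate and delay the first
activation, with MTE hit more mildly than Inr/DPE; extra Zelda sites
shorten the onset delay.  Absolute rates for these promoters are not known;
only the orderings should be relied on.

## Analysis pipeline

**Projection and crop.**  Per time point the histone stack is
max-projected.  Optional centered crops mirror common practice of removing
edge nuclei (430/512 square, or a 300×430 dorsoventral band).

**Segmentation, method 1.**  Gaussian smoothing (sigma 2 px) → white
top-hat (disk radius 15 px) → CLAHE → Otsu threshold → hole filling and
small-object removal → distance-transform watershed with seed maxima at
least `min_distance` apart (default 5 px ≈ half a nucleus radius).  All
sizes live in config; the defaults suit nuclei of ~9 px radius.

**Segmentation, method 2.**  Gaussian blur; pixels above 95% of the global
maximum (saturated chromocenters) replaced by their local 3×3 median; then
a threshold scan.  Each candidate threshold is scored by (i) closeness of
the connected-component count to the expected nucleus count and (ii) a size
term — the fraction of components with areas outside 0.3–3× the median
component area at the Otsu threshold, plus the relative departure of the
median area from that reference.  The best-scoring (lowest) threshold wins;
ties go to the lower threshold.  The expected count defaults to the
previous frame's count (temporal continuity), or the Otsu component count
on the first frame.  The exact scoring function is a package choice and is
deliberately isolated and swappable.  Afterwards, MS2 transcription dots
(pixels above 2× the MS2-channel mean, minimum blob size 4 px to ignore
single-pixel noise) that fall outside every nucleus trigger a refinement:
the nucleus whose pixels are nearest to the dot centroid is dilated, never
into other labels, until the dot is covered.  Finally labels are clipped to
the Voronoi cells of the component centroids, which guarantees disjoint
labels.  Manual mask correction is replaced by `apply_override`.

**Tracking.**  Adjacent frames are matched greedily in ascending
centroid-distance order, forward and backward, keeping only assignments on
which both passes agree; any displacement above `max_disp` (default: one
nucleus radius — some gate is needed to prevent teleporting lineages) is
refused.  Greedy matching, not optimal assignment, is the faithful
implementation of a per-nucleus minimum-distance rule; it is deterministic
under ties (lower label wins).  Gaps of up to 2 missing frames (e.g. a
dropped or empty frame during z-correction pauses) are bridged and flagged;
longer gaps split the lineage.

**Spot quantification.**  The transcription site is the brightest voxel of
the raw 3-D MS2 stack among voxels over the nucleus's projected footprint
(the footprint owns all z-planes; ties break to the lowest z, then
row-major).  A 2-D Gaussian `alpha + I0 exp(-((x-x0)^2/2sx^2 +
(y-y0)^2/2sy^2))` is least-squares fitted in an 11×11 window at the spot's
z-plane, initialized with alpha = window-border median, I0 = center minus
alpha, sigmas at 1.5 px.  Bounds: 0.3 ≤ sigma ≤ 8 px and I0 ≥ 0 for
numerical stability, and the fitted center may move at most a quarter
window from the located pixel — without that constraint the fit can latch
onto a neighboring nucleus's dot entering a window corner when the nucleus
itself is silent.  For the same reason the fit only uses window pixels
assigned to the nucleus under analysis (its own label, plus background
pixels nearer to its centroid than to any other nucleus's), the standard
nearest-region assignment.  The solver is trust-region least squares with
the analytic Jacobian and a 400-evaluation cap: a genuine dot converges in
well under 100 evaluations, and fits that have not are dotless noise
windows that end up excluded regardless.  The spot intensity is the closed-form background-
subtracted integral `2*pi*sx*sy*I0`.  A fit is invalid when the solver
fails or the dot extent exceeds the window (2 sigma > window/2 on either
axis — the window is 11 px, so sigma > 2.75 px; "extent" had to be
operationalized and this is the documented proxy).  Invalid fits exclude
that nucleus's time point: the value is linearly interpolated so smoothing
stays defined, but flagged frames never enter totals.  Each trajectory is
baselined by subtracting its minimum over valid frames.

**Burst calling.**  Trajectories are smoothed with a centered 5-frame
boxcar (truncated at the edges).  One threshold serves each experiment
set; its default is 10% of the group's maximum smoothed intensity — the
same rule used to classify instantaneously active nuclei, adopted for the
burst start for internal consistency since no separate number is
specified.  Scanning left to right: a burst opens above threshold, tracks
its running local peak (the only causal reading of "local peak"), and
closes at the first frame strictly below 55% of that peak (ties at exactly
55% do not close it); the interval then shifts 2 frames later (clamped at
the trace end; a burst pushed entirely off the end is dropped); bursts
shorter than 5 frames are detection noise; and a burst opening at frame 0
on a strictly decreasing 5-frame run is a decaying tail from before the
observation window, not a burst.  Scanning resumes at the closing frame.
Shifted intervals cannot overlap except through end-clamping, where they
merge.  Per nucleus: amplitude = mean over bursts of the smoothed-trace
peak; duration = mean burst length; total output = rectangle-rule area
under the *raw* trajectory over the whole window (the trajectory, not only
in-burst frames); t_first = first burst onset; induction rate = bursts per
minute after t_first.

**Population metrics.**  Activity threshold = 10% of the group maximum;
instantaneous and cumulative active fractions and the mean ± SD intensity
over instantaneously active nuclei are reported per frame.

**Dwell-time fits.**  ON/OFF durations are fitted by maximum likelihood
(exponential rate = 1/mean) with a Kolmogorov–Smirnov test against the
fitted distribution.  OFF durations from telegraph simulations should pass
(burst initiation is one rate-limiting step); ON durations generally do
not — partly because multi-step switch-off kinetics are non-exponential,
and partly because the calling rules themselves impose a minimum length
and add the reporter's dwell, so the ON-duration test is only meaningful
as a negative control.

**Autocorrelation.**  Per nucleus: smooth (5-frame boxcar) → first
difference (removes slow trends across the nuclear cycle) → biased sample
autocorrelation on the integer-frame lag grid → normalize to 1 at the
smallest reported lag.  The default normalization lag is 0 of the
derivative series.  Normalizing at lag 1 instead (selectable in config) is
numerically fragile: differencing a 5-frame boxcar leaves near-zero lag-1
autocovariance for serially uncorrelated traces, so dividing by it
explodes on null-like data.  The null reference shuffles each trajectory's
time axis (seeded; the seed is recorded in the result) and computes plain
normalized autocorrelation *without* re-applying smoothing and
differencing: a shuffled trace is white, and the filter would only
re-imprint its own autocorrelation signature (exactly −0.5 at a lag of one
window), masking the flatness the null is supposed to display.  The
periodicity estimate is the lag of the first local maximum beyond the
initial anti-correlation dip of the mean curve.

**Reconstitution.**  Each frame's raw MS2 intensity is a production proxy
(raw, for consistency with total output).  The default decay is
first-order with a 7-minute half-life: remaining = Σ_f I(f)·Δt·2^(−(t_end −
t_f)/t_half).  A literal linear-cohort model (each cohort decays linearly
to zero over two half-lives) sits behind a flag; "linear degradation with a
half-life" is self-contradictory, and both models retain exactly half of a
cohort one half-life after synthesis.  Decay is discretized per frame; at
Δt ≤ 16.8 s versus continuous compounding the difference is below 0.2%.
Nuclei tracked into the final frame are false-colored with intensity
proportional to their remaining amount and overlaid on the histone
projection.

## Validation experiments and problem sizes

The acceptance script (`scripts/acceptance.py`) and
`tests/test_acceptance.py` run the same experiments:

* **Burst-caller equivalence**: 500 telegraph traces spanning wide
  parameter ranges, compared burst-for-burst against an independently
  written scalar transcription of the calling rules.
* **Frequency/amplitude dissociation**: 300 nuclei per condition at
  `k_on = 0.10/min`, `k_off = 1/min`, `r_load = 60/min`, `dwell = 0.8 min`,
  75-minute traces at 16.8 s/frame.  Halving `k_on` should halve the called
  burst frequency and leave amplitude unchanged; halving `r_load` the
  converse.  The regime deliberately puts activation far into the
  rate-limiting position (`k_on ≪ k_off`): burst frequency saturates at
  `k_on·k_off/(k_on+k_off)`, so when the two rates are comparable no caller
  could report a clean factor of two; the short dwell additionally limits
  the merging of consecutive bursts whose gap falls inside the smoothing
  window, which deflates the count of the higher-frequency condition.
* **Dwell-time shape**: 60 nuclei, 120-minute traces at 12.8 s/frame,
  `k_on = 0.10/min`, `dwell = 0.6 min`.  Long traces limit right-censoring
  of OFF periods; the short dwell keeps the reporter's persistence from
  contaminating OFF durations.  The called OFF durations are KS-tested
  against a single exponential and the ML rate compared with `k_on`; the
  smoothing window and burst-end rule shorten measured OFF gaps by roughly
  2–3 frames, which is the dominant residual bias.  ON durations from the
  same regime with a 4-step switch-off serve as the negative control.
* **Imaging round trip**: a 400×400 px, 100-nucleus, 200-frame movie
  (radius-9 disks, drift 0.3 px/frame).  Noiseless: every trajectory must
  match ground truth within 1% of its dynamic range at every non-excluded
  frame.  With pixel noise (SD 50): fraction of nuclei at IoU ≥ 0.7 for
  both segmentation methods (method 2 on every 25th frame: its per-frame
  cost is higher and the check is a per-frame quality measure, so sampling
  frames repeats the same measurement rather than adding information) and
  lineage accuracy of full-length tracks.
* **Periodicity**: 400 square-wave bursting trajectories of period 20
  frames with random phases; the mean autocorrelation must peak at 20 ± 1
  frames while the shuffled null stays below 0.1 in magnitude beyond lag 1.

These sizes were chosen as the smallest cohorts at which the sampling error
of each measured quantity is comfortably below the tolerance being checked.

## Known limitations

* One allele per nucleus: two dots in a nucleus are not resolved; the
  brighter wins.
* Greedy tracking has no motion model and will not survive large jumps;
  the gate refuses rather than guesses.
* The burst caller's measured ON durations include the reporter dwell and
  the smoothing width; they are comparable across conditions but are not
  unbiased estimates of promoter ON times.
* The threshold scan of segmentation method 2 assumes roughly homogeneous
  nucleus sizes within a frame.
* The method-2 spot refinement can, in principle, be undone by the
  subsequent Voronoi clipping if a dot lies nearer a neighbor's centroid;
  with dots inside or near their own nucleus this does not arise.
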