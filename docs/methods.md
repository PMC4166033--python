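# Methods

This note documents the models, defaults and numerical conventions of
the package, the design choices made where the procedure was genuinely
open, and what the synthetic-data tests do and do not establish about
real recordings.

## Trace model and dF/F

A raw trial trace is modeled as
`F(t) = B₀ · (1 + m·t) · (1 + r(t)) + ε(t)`, where `B₀` is the resting
fluorescence (default 1000 a.u.), `m` a slow drift slope (per second),
`r(t)` the calcium dF/F signal and `ε` white Gaussian noise expressed in
dF/F units (default SD 0.01). The signal is a train of whisk-locked
transients — 10 cycles at 5.5 Hz over a 2-s stimulation window — each
with instantaneous rise and single-exponential decay. The decay constant
defaults to 0.8 s, deliberately above the 650-ms neuropil-exclusion
threshold so that the default population passes the decay gate; no
biophysical spike-to-calcium model is attempted. The transient train is
normalized so its 10-sample windowed peak equals the specified amplitude
exactly, making amplitude recovery through the processing chain a sharp
test (noise-free recovery is exact to discretization, verified to
< 1% relative error).

dF/F uses the lowest 10% of the trace's own samples as baseline. The
"lowest 10% of pixels" rule is interpreted per cell and per trial over
time samples, since a line scan yields one pixel stream per cell. The
1-s pre-stimulus window of `R` is then fitted with a straight line which
is subtracted over the whole trace; for a purely multiplicative linear
drift this removes the ramp exactly (machine precision), which the tests
assert.

Sampling intervals are nominal line-scan values (10–17 ms; default
12 ms). Trials of unequal length are truncated to the shortest before
averaging. The 10-sample peak window is centered on the argmax of the
trial-averaged trace (4 samples before, 5 after), clipped at the trace
edges, ties broken toward the earliest index. Per-trial peaks are read
at the average's window rather than each trial's own argmax so that the
responsiveness comparison uses like-for-like windows; the per-trial
argmax variant is available behind `peak_mode="own_argmax"`. Response
area is the trapezoidal integral over the stimulation window.

## Statistical gates

*Responsiveness*: one-way ANOVA between per-trial windowed peaks and
per-trial pre-stimulus means, at α = 0.01, with the extra requirement
that the mean peak exceed the mean baseline; zero variance in both
groups counts as non-responsive. Placing the window at the argmax of the
averaged trace selects slightly upward noise under the null, so the
realized type-I error runs marginally above nominal (≈1.5% at the
default 30 trials and ~400 samples); this is inherent to the windowed
argmax rule and is measured, not hidden — the calibration test asserts
the rate stays within the binomial 99% CI of α. An `all_samples` variant
(pooling window samples instead of per-trial summaries) is provided
behind a flag.

*Decay exclusion*: a single exponential `A·exp(−(t−t₀)/τ) + c` is fitted
to the post-stimulus segment of the averaged trace from its
post-stimulus maximum onward; neurons with τ < 650 ms are excluded.
Non-convergent fits are kept and flagged rather than silently dropped.
The decision is made per neuron on the largest-peak condition: weak
non-preferred responses give unreliable τ estimates, and the exclusion
targets neuropil contamination of the cell, not of a single condition.

*Stability*: per condition, per-trial peaks of the two time-segregated
blocks are compared with a Welch two-sample t-test (the block comparison
is specified only as a p < 0.01 exclusion; Welch is the robust default);
an experiment passes only if no condition differs at α = 0.01.

*Selectivity*: SI = (max − min)/max over per-condition peaks (and,
independently, areas); preferring requires SI ≥ 0.35 — the inclusive
boundary, configurable — and an omnibus p < 0.01 across conditions on
per-trial peaks, using ANOVA when Levene's test accepts equal variances
at α = 0.05 (no level is stated for the variance gate; 0.05 is the
conventional default) and Kruskal–Wallis otherwise. When a free-whisk
condition is present it enters the SI by default; a condition subset can
be passed. Neurons whose peak- and area-based preferred textures differ
are flagged discordant and can be excluded, mirroring the original
exclusion of such rare cases.

## Spatial statistics

The measured k-neighbor probability is the fraction of labeled neurons
whose k nearest labeled neighbors *all* share their preferred texture;
the all-of-k reading reduces at k = 1 to the printed closest-neighbor
formula and produces a monotonically decreasing curve in k. An any-of-k
variant is available behind a flag. Distance ties are broken by neuron
index. The closed-form chance level applies to k = 1; for k ≥ 2 the
chance level is estimated by label permutation over the fixed positions.

The Monte-Carlo clustering test redraws all neuron positions uniformly
over the recording region (keeping per-label counts), pools the
intra-group mean distances of all labels over 1000 runs into one null
histogram, and takes its 5th percentile as the significance threshold;
a label clusters when its observed mean intra-group distance falls
below it. The region defaults to the convex hull of the observed
positions but should be the true recorded field when known (it is passed
explicitly wherever the generator's geometry is available): a hull or
observed bounding box systematically underestimates the field and makes
the test conservative — with the true field supplied, the false-positive
rate calibrates at the nominal 5% (asserted within the binomial 99% CI
over 200 replicate maps).

Columnar consistency for multi-contact electrode data reports the
fraction of penetrations whose sorted units all share one preferred
label against the label-frequency expectation Σ_k f_k^m, plus a
retention curve relative to the most superficial contact's dominant
label, computed only where that contact is dominated at ≥ 66%.

## Normalized barrel and maps

The canonical barrel is a unit circle with the MC-LR (medial-caudal to
lateral-rostral) diagonal at 45°. Each experiment supplies its barrel
outline and two anatomical anchor points; the transform translates their
midpoint to the origin, rotates the anchor axis onto the diagonal, and
scales the outline's half-extents along and across that axis to 1
(similarity plus anisotropic scale). How barrels from different animals
were originally co-registered is not specified anywhere; this anchor
convention is the package's own declared choice. Affine maps preserve
point-in-polygon membership, which is tested.

Texture maps are evaluated analytically (separable Gaussian per neuron,
no kernel truncation) on a 300 × 300 px raster spanning 1.25 barrel
radii, so σ = 15 px retains its published pixel scale. The
normalization `M_norm = M/(ε + Σ_t M_t)` uses
ε = 10⁻⁶ · max(Σ_t M_t) ("a small number preventing division by zero"
made concrete); the mixed color map renders pixels white where
Σ_k M_norm < 0.05. Per-pixel sums of normalized maps deviate from 1 by
< 1% wherever the raw sum exceeds 100ε.

## Kinematics and spectra

Whisker tracking points are interpolated with a cubic spline
(chord-length parameterization) and resampled at 200 equally spaced
arc-length positions before backward differencing — the spline-then-
difference order follows the tracking convention; the density of 200 is
a declared default. Base angle is `arctan2(ẏ₂, ẋ₂)`; curvature
`κ = |ẋÿ − ẏẍ|/(ẋ² + ẏ²)^{3/2}` with zero-tangent points excluded from
the maximum with a warning. Circle curvature is recovered to ≪ 1% at
the default density.

Slip-stick events are local maxima of the absolute central-second-
difference acceleration; counting events above a sliding threshold is
then monotone non-increasing by construction. The default low band
(4–9) and high threshold (≥ 28) are in position-units/ms²; published
figure legends mix µm/ms² and mm/ms² for the high threshold, so units
are configurable and not resolved here.

The vibration PSD uses Welch's method with Hann windows, 50% overlap and
segment length 254 so that exactly 128 one-sided frequency bins enter
the power centroid Σ S(f)·f / Σ S(f). A pure tone is recovered within
one bin (≈ 39 Hz at 10 kHz sampling); white noise lands at half-Nyquist
within 5%.

## Acquisition support

Scan timing follows the printed free-hand line-scan formulas: period =
n · dwellTime + max(X-return, Y-return) with return times
|endpoint difference|/galvo speed. Image drift is measured by
FFT-based cross-correlation against a time-averaged template; linear
(zero-padded) correlation is the default to avoid wrap-around, with the
circular variant retained for the synthetic identity tests; shifts are
reported at integer-pixel resolution (no sub-pixel refinement, matching
the pixel-level QC it reproduces). Constant images are rejected as
structureless rather than returning an arbitrary peak.

## Synthetic populations

The generator emulates the study conditions: ~50 neurons per field,
four textures (optionally free whisk), 30 repetitions split into two
blocks, 55% selective / 20% non-responsive by default, planted
selectivity SI = 0.6 (preferred amplitude 1, others 0.4). Counts are
apportioned by largest remainder with a seeded tie shuffle. Selective
neurons form disjoint clusters (centers rejection-sampled with pairwise
separation ≥ 2 radii) inside the barrel polygon; non-selective neurons
scatter uniformly. Per-neuron amplitude heterogeneity, correlated noise,
neuropil contamination, photon shot noise and motion artifacts are *not*
modeled, so passing recovery tests demonstrates correctness of the
statistics under the declared model, not robustness to every property of
real two-photon data. Problem sizes in the test suite (e.g. 200
replicate maps for null calibration, 1000 null neurons for type-I error,
60-neuron populations for fraction recovery) were chosen to give
meaningful binomial confidence intervals at interactive runtimes.

## Known limitations

* The responsiveness null rate is slightly above nominal by
  construction (windowed-argmax selection); see above.
* The Monte-Carlo clustering test is conservative when the recording
  region must be estimated from the observed positions.
* The normalized-barrel transform is a declared convention; absolute
  diagonal/radial statistics depend on it.
* Spike-train inference from calcium, motion correction of raw movies,
  and video-based whisker detection are out of scope; tracked points,
  barrel outlines and sorted spikes are inputs.
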