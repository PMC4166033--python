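# texturemap

Analysis pipeline for texture-coarseness coding in rat barrel cortex, as
measured with two-photon calcium imaging during whisking against
sandpapers of graded coarseness (P120–P1000 grit). The package turns raw
per-neuron line-scan fluorescence traces into texture-selectivity
classifications, spatial-clustering statistics, and normalized-barrel
preference maps, and bundles the supporting whisker-kinematics,
vibration-spectrum, and acquisition-timing computations. Because no raw
recordings are publicly available, a first-class synthetic-data module
generates every input with known ground truth, so the whole chain is
testable end to end.

It is written for systems neuroscientists who want a reproducible,
scripted version of this style of population-imaging analysis, and for
methodologists who want calibrated null behavior for its statistical
gates.

## The analysis in brief

For each neuron *j* and trial, the relative fluorescence change is

    R_j[t] = (F_j[t] − B_j) / B_j,

with the baseline *B_j* the mean of the lowest 10% of that trace's
samples; a line fitted to the 1-s pre-stimulus window is subtracted to
remove slow drift. Trials are averaged per texture *k*, and the response
peak *P_jk* is the mean of 10 samples around the maximum of the averaged
trace (the area over the whisking train is computed in parallel).
Neurons whose evoked peak differs from the pre-stimulus baseline (ANOVA,
p < 0.01) are responsive; neurons with fitted decay constants below
650 ms are excluded as neuropil-dominated, as are experiments whose two
stimulation blocks differ (p < 0.01).

Texture selectivity uses the selectivity index

    SI_j = (max_k P_jk − min_k P_jk) / max_k P_jk,

and a neuron is *preferring* when SI ≥ 0.35 and the per-condition trial
peaks differ by an omnibus test (ANOVA when Levene's test accepts equal
variances, Kruskal–Wallis otherwise; p < 0.01).

Spatial clustering of preferred textures is quantified two ways:

* the probability that a neuron's *k* nearest labeled neighbors all
  share its preferred texture, against the chance level
  `P = Σ_k (N_k/ΣN)(N_k/N_total)`;
* a Monte-Carlo test comparing each label's mean intra-group distance
  `D_AA = Σ_{j,k∈A} d_jk / (|A|(|A|−1))` with the 5th percentile of
  1000 uniform position redraws.

Maps from different animals are projected onto a canonical "normalized"
barrel (unit circle, medial-caudal→lateral-rostral diagonal at 45°),
smoothed with a σ = 15 px Gaussian per texture,
`M^k(x,y) = Σ_i exp(−((x−x_i)² + (y−y_i)²)/2σ²)`, normalized per pixel
and mixed into a color map. Whisker kinematics (base angle, discrete
curvature, slip-stick events), vibration power centroids over a 128-bin
Welch PSD, free-hand line-scan timing, and FFT-correlation drift
measurement round out the chain.

## Worked example

```bash
python analysis/01_simulate_experiment.py
python analysis/02_process_traces.py
python analysis/03_classify_selectivity.py
python analysis/04_spatial_clustering.py
```

The simulated experiment plants 50 neurons — 55% texture-selective in
four spatial clusters, 20% non-responsive — and prints, after
processing:

```
recovered partition (%): {'preferring': 54.0, 'non-preferring': 24.0, 'non-responsive': 22.0}
peak/area concordance of preferring neurons: 100.0%
preferring neurons matching their planted texture: 100.0%
mean SI of preferring neurons: 0.62 (planted 0.60)
```

i.e. the chain recovers the planted 55% preferring fraction (54% after
the statistical gates), every recovered preference matches its planted
texture, and peak- and area-based preferences agree. The clustering step
then reports

```
k=1: measured 100.0%  vs  chance  22.5%
closed-form expected (k=1): 17.4%
Monte-Carlo 5% threshold distance: 77.0 px
  P120: observed intra-group distance   18.7 px -> clustered
```

— the planted clusters sit far below the uniform-null threshold, and the
closest-neighbor probability is far above chance, exactly the signature
the statistics are designed to detect. Scripts 05–07 add the
normalized-barrel maps and the kinematics/vibration/acquisition checks.
The same steps are available as a CLI (`texturemap simulate`, `process`,
`select`, `cluster`, `map`, `kinematics`, `vibration`, `qc-shift`).

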