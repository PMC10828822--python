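# Methods

## Scope and data model

`tmtd` operates on three inputs: a PSM table (one identified MS2 scan per
row with precursor descriptors, reporter intensities and MS2 TIC), a
spectral snapshot table of centroided MS1 peaks with per-peak noise
values (the information a vendor raw-file extractor provides; a narrow
mzML route fills the same structure when the file exports noise arrays),
and a channel layout (channel names, reporter m/z, isotopic impurity
matrix, design groups, and the sets of empty and interference-only
channels). Built-in reporter m/z tables cover TMT 10/11-plex and TMTpro
16/18-plex; custom layouts are TOML/JSON configs.

## Purity and signal metrics

**PPF.** For each PSM the two MS1 scans bordering its MS2 scan are
searched inside the closed isolation window `precursor_mz ± width/2`
(uniform isolation efficiency is assumed across the window). The
precursor is located at the declared m/z within ±0.0025 Th; if the
preceding scan lacks it, the second-last MS1 scan substitutes (its own
retention time is then used for the weight); failing that, the precursor
is imputed at the declared m/z with the minimum observed peak intensity
of that scan. The following scan is skipped when its window is empty or
when the precursor was found on neither side; a non-empty following
window without the precursor gets the same minimum-intensity imputation
from its own scan. Peaks at ±1.00335484/z (±0.00125 Th) are flagged as
precursor isotopes — a literal ±1 Th offset would miss isotopes of
multiply charged precursors, and only ±1 isotopes are flagged. Scan
weights are `w_i = 1 − d_i / Σd_i` with `d_i` the absolute RT difference
to the MS2 scan; a single usable scan receives weight 1 (the formula
degenerates to 0 there, but that scan must carry all information). PPF
is the precursor-flagged share of the weighted window intensity, TIW the
weighted total.

**PIC** is the MS2 TIC minus the summed reporter intensities, clamped at
0 with a warning for pathological inputs. **OIL**, available only in
ground-truth designs, is the mean normalized intensity of the
interference-only channels over the mean of the remaining peptide
channels, capped at 1; both averages skip missing values. The
denominator set comes from the layout, not from any hard-coded channel
list.

**Reporter inference and impurities.** Reporter intensities are the
maximum peak intensity within a closed ±0.002 Th window around each
reporter m/z (centroided MS2 data assumed); absent peaks are missing, an
explicit 0 stays 0. Isotopic impurities are removed by solving
`observed = M · true` exactly and clamping negative solutions to 0;
missing channels are imputed as 0 for the solve and restored to missing.
Impurity correction runs before between-sample normalization.

## Hidden-ion noise regressor

Per run, a Gaussian-product KDE of the (m/z, RT) coordinates of distinct
(sequence, modifications, charge) features — each placed at its
maximum-reporter-sum PSM — is evaluated on a 200×200 grid. Bandwidths
follow the normal reference rule `1.06·min(sd, IQR/1.349)·n^(−1/5)` per
axis (overridable); the grid spans the feature range padded by one
bandwidth per axis so border features are not starved. The field is
rescaled to sum to 1, zeros are replaced by the minimum positive value,
and the square root is taken, in that order — the root damps extreme
density contrasts. Values are interpolated bilinearly with out-of-range
coordinates clamped to the border. The PSM's `noiseEstimate` is the mean
noise value of the preceding-scan isolation-window peaks times the
interpolated density at (precursor m/z, MS2 RT); an empty window falls
back to the nearest peak in m/z of that scan, noise floors being locally
smooth.

## Empirical peptide classes

The fragmentation-efficiency response is `log(total reporter / (PIC·PPF))`.
Features are the charge category (1/2/3, higher charges pooled), the TMT
label count (N-terminus plus lysines), presence of H, R, K, E, D, an
extra-charge flag (charge exceeding one proton plus one per R and H),
and any variable modification present in more than `min_leaf` PSMs. The
tree grows greedily: every admissible binary split (ordinal variables by
≤ threshold, booleans by level) is scored by the summed within-child sum
of squares; ties break by a fixed variable order then the smaller
threshold, making refits bit-identical. Splits leaving a child with
≤ 100 PSMs are rejected. A split must additionally remove at least
`min_gain` (default 1%) of the root sum of squares: with a continuous
response, almost every split reduces sample variance slightly, so a
literal "stop when no split reduces variance" rule would grow
noise-driven leaves down to the occupancy floor and shred the real class
structure; the gain floor is the standard complexity control for this
family of algorithms. Classes are refit per dataset and never cached —
their composition varies with collision energy, chromatography and
sample type. Variance minimization is unweighted.

## Robust fit and EIL

Designs are intercept-free with interaction encoding: one column per
(precursor × class), one per (nonprecursor × charge), one noise column.
Charge categories with fewer than 25 observations merge into the nearest
category. Fitting is IRLS M-estimation with Tukey bisquare ψ (c = 4.685),
MAD residual scale (×1.4826), at most 50 iterations, coefficient
convergence 1e-8 — the conventional defaults of this estimator family —
run separately per raw file and per FAIMS compensation voltage. Aliased
columns are dropped via pivoted QR with a warning; non-convergence
returns the last iterate, flagged; negative coefficients are retained
(only EIL is clamped). The ground-truth model (response = summed
interference-only reporter signal, regressors `TIW·(1−PPF)` per charge
plus noise) exists for validation against OIL; EIL is always computed
from the general model as one minus the fitted precursor share of the
fitted total, clamped to [0, 1], missing when the fitted total is not
positive.

## Correction and site-to-protein normalization

Between-sample normalization uses median-ratio size factors on log2
intensities (the reference is the mean log2 over channels of rows
quantified everywhere) and transforms back to the linear scale; cyclic
LOESS is a recognized alternative but size factors are deterministic and
dependency-light. Correction subtracts, per PSM, the mean over non-empty
channels (missing values excluded) times `min(EIL, 0.8)`; the 0.8 cap
mitigates overcorrection. Corrected or missing values below the
spectrum-wise minimum observed MS2 peak intensity are replaced by that
minimum; when no MS2 peak list is available the minimum non-missing
reporter intensity of the scan stands in. Correction is deliberately not
idempotent — applying it twice over-corrects.

For PTM analysis, PSM intensities are summed to protein groups
(unmodified peptides only) and PTM sites, with EIL aggregated as the
intensity-weighted mean (features quantified by FAIMS-MS3 get EIL 0).
For each site/protein pair the partner with the lower EIL receives a
uniform addition `mean(I)·(1−EIL_low)/(1−EIL_high) − mean(I)` on every
channel, which equalizes the implied interference levels while barely
perturbing the quantitative profile; per-channel ratios are then divided
by their median so the median ratio is 1. Pairs whose higher EIL is 1
are skipped. Sites matching several protein groups normalize against the
group with the most quantified PSMs (ties alphabetically), with a
warning. The channel-mean set includes the interference-only channels —
they carry background peptide and are non-empty.

## Synthetic benchmark generator

The generator reproduces the two-proteome spike-in design: a background
proteome in all 12 peptide channels, a spiked proteome at relative
amounts 0:18:27:36 across four three-channel groups, channel 126C
labeled without peptide, three channels unused, and a
background-to-spike mass ratio of 10. Reporter signal is generated
exactly from the causal model, so the planted coefficients are the
estimand, and MS1 snapshots are emitted such that PPF, TIW and
`noiseEstimate` recomputed by the pipeline reproduce the drawn values to
float accuracy. The hidden-noise component never appears in the peak
lists — the mechanism that makes `1 − PPF` under-predict observed
interference.

Default conditions and their rationale:

* **Intensity**: total isolation-window current lognormal, split into a
  protein-persistent effect (log-sd 0.7) and a PSM-level effect
  (log-sd 0.45). Drawing the *window total* rather than the precursor
  intensity avoids amplifying contaminated windows by 1/PPF, which would
  tie the residual scale to the non-precursor column. Spike PSMs are
  scaled by the mass ratio and the species PSM fractions; the spike PSM
  fraction defaults to 0.1, consistent with a 10:1 mass ratio.
* **Purity**: PPF ~ Beta(3, 1.5) with impurity odds scaled by
  (reference/intensity)^0.5 — weak precursors sit in relatively dirtier
  windows. This link gives proteins persistent interference
  susceptibility, which is what makes aggregation to protein level
  *improve* the OIL correlations of both EIL and 1−PPF, as observed on
  real data.
* **Noise floors**: lognormal around 5e3 with log-sd 1.1. The spread
  matters: a near-constant noise regressor behaves like an intercept and
  absorbs the skew of multiplicative noise under the robust loss, biasing
  its coefficient upward.
* **Measurement noise**: scalar lognormal with log-sd 0.3 and median 1
  (the robust fit targets the conditional median), plus per-channel
  jitter with log-sd 0.15 and *mean* 1 — channel noise is summed into the
  reporter total, so a median-1 channel law would inflate it
  systematically. Optional gross outliers multiply the scan by 100.
* **Interference geometry**: channel-uniform by default
  (`interference_uniformity` exposes a loading-weighted alternative);
  the hidden share of interference per PSM varies widely. When
  `interference_share` pins the mean interference fraction, the hidden
  part is drawn independently of the precursor scale (a proportional
  draw would alias the noise and precursor columns) and the purity is
  solved in closed form to hit the per-PSM target.
* **Fragmentation classes**: two planted classes on arginine content
  (yields 0.14 vs 0.06 of PIC), a four-class variant adds a
  missed-cleavage lysine axis; charge-specific non-precursor yields
  0.085/0.11.

What the generator does not emulate: chromatographic elution shapes,
real fragment spectra, isotopic impurity leakage (identity matrix by
default), search-engine behavior, or non-ideal isolation efficiency
profiles. Passing tests on these simulations therefore demonstrates the
estimator's correctness under its own model assumptions plus realistic
noise, not performance on any particular instrument's data.

## Evaluation harness

Ground-truth reports compute Pearson correlations of OIL with EIL and
with 1−PPF at PSM level and after protein aggregation (intensities
summed; EIL/PPF intensity-weighted), and design fold-change recovery
before and after correction. Fold changes are medians of per-feature
log2 ratios of group means, reported at protein level (summed corrected
PSM intensities) with PSM-level medians alongside — protein-level sums
suppress channel-level noise, mirroring how such benchmarks are read.
Differential-expression checks use Welch's t-test on log2 intensities
with ROC curves over significance thresholds; moderated testing is out
of scope and unnecessary for shape comparisons at these sample sizes.

## Numerical notes and limitations

* Problem sizes: unit tests simulate 600–2000 PSMs; the end-to-end
  property checks use 5000–10000 PSMs per run, where coefficient recovery
  is comfortably inside 10% and the per-PSM EIL error is ~0.01–0.02.
* Median-ratio normalization partially absorbs spike-group differences
  when the fraction of structurally deviating rows and the channel noise
  are large; this is a property of the estimator itself, visible on real
  data too, and bounds how exactly design ratios can be recovered after
  correction.
* The robust fit is mildly biased (few percent) under strongly
  heteroscedastic multiplicative noise because a single residual scale
  down-weights high-intensity scans; EIL, being a ratio of fitted parts,
  is much less affected.
* Ties at reporter-window edges are included (closed intervals);
  overlapping reporter windows raise a configuration error rather than
  guessing.
* EIL is undefined (missing) when the fitted total is non-positive;
  correction skips PSMs without EIL or without any quantified channel.
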