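# Methods

This note records the models, conventions and design choices behind
`spncat`, and what its synthetic-data tests do and do not establish.

## Data model and conventions

A catalogue is a montage plus experiments; each experiment holds one
trial-averaged epoch per participant per condition (microvolts), with a
designated (regular, random) contrast pair and metadata: sample size `n`,
`W` (regularity salience on [0, 1]), `Task` (0/1 task relevance), and a
published flag. Epochs default to −200…2000 ms at 128 Hz, baseline
corrected over [−200, 0) ms.

* **Time windows** are half-open `[start, end)` in ms and map to sample
  indices by `ceil((t − epoch_start) · rate / 1000)` at both ends. The
  mapping is idempotent under window concatenation: `[a,b) ∪ [b,c)` covers
  exactly the samples of `[a,c)`.
* **Sign convention:** SPN = regular − random, so a symmetry response is
  negative. Directional proportion counts `diff < 0`; exact zeros count as
  non-directional, which is conservative for the sign test.
* **Cluster averaging** is a plain arithmetic mean over the electrode
  subset (equal weights, hemispheres not re-weighted).
* **Montage:** the bundled 64-channel layout takes mne's standard Biosemi-64
  positions, normalised to the unit sphere. Electrodes are neighbours iff
  their great-circle distance is ≤ 0.55 rad — a configurable threshold
  chosen so the median neighbour count is ~7 (the 6–8 range typical of
  64-channel caps). The 10-05 layout never defines adjacency; this is the
  package's convention.
* **Interchange format** is plain JSON + TSV (17 significant digits, so a
  save/load round-trip is bit-faithful at float64 precision). Binary EEG
  formats are out of scope; stage i–iv preprocessing (filtering, ICA, trial
  rejection) is assumed done upstream.

## Effect size and power

The within-subject effect size is Cohen's `d_z` = mean(diffs)/SD(diffs)
(SD with denominator n−1). Power of the two-tailed one-sample t-test is
computed exactly from the noncentral t distribution: with noncentrality
`ncp = |d|·√n` and `df = n−1`,

    power = P(T′ ≥ t₁₋α/₂) + P(T′ ≤ −t₁₋α/₂),  T′ ~ nct(df, ncp).

No normal approximation is used anywhere in the solver; the required-`n`
search brackets by doubling then scans to the exact boundary, capped at
10⁶. The second rejection region matters only at tiny `d` but is kept for
exactness (at `d = 0` power equals α to machine precision).

The amplitude → `d_z` map is an ordinary least squares quadratic
`d̂ = a·x² + b·x + c`. A quadratic rather than a line because, empirically,
effect size saturates for strong SPNs — between-participant variability
grows with the mean response. The generator exposes that mechanism as a
`heteroscedasticity` slope (SD multiplied by `1 + h·|amp|`), off by
default.

The sign-test threshold doubles the upper binomial tail: smallest `k` with
`2·P(X ≥ k) ≤ α`, `X ~ Binomial(n, ½)`. Tail-doubling (not the
sum-of-smaller-probabilities "exact" method, which is available as an
option) is the default because it reproduces the standard 18/24 and 32/48
thresholds.

The one-way repeated-measures ANOVA uses the classic SS decomposition with
participant blocking and no sphericity correction (Greenhouse–Geisser is
deliberately not applied; with two conditions F = t² exactly). Observed
power follows the post-hoc convention `ncp = F·df₁` on the noncentral F —
reported because it is what common packages print, and documented as a
descriptive transform of the p-value, not an inference.

## Publication-bias diagnostics

Group comparisons use Welch's t (Satterthwaite df, equal variances not
assumed) and a Mann–Whitney U (scipy's exact/asymptotic policy).
Study-level pooling is DerSimonian–Laird random effects: moment estimator
τ² = max(0, (Q − df)/c), weights 1/(se² + τ²), normal-quantile 95% CI.
A fixed-effect option exists. Per-study confidence bands in the cumulative
distribution use t critical values (matching the one-sample t-test
exactly: the CI excludes zero iff p < .05); funnel-plot significance flags
use normal critical values, matching the straight funnel-triangle edges.
Funnel asymmetry is Egger's classic regression of the standard normal
deviate (mean/se) on precision (1/se), two-tailed t on the intercept with
k−2 df. Egger's test is known to be mildly anti-conservative; the suite
tolerates a type-I rate up to ~10% at nominal 5%. Trim-and-fill, selection
models and p-curve are out of scope.

## Spatio-temporal cluster permutation test

Pointwise one-sample t statistics are computed at every (electrode,
sample). Points with |t| at or above the two-tailed critical value at
`cluster_alpha` (default .05, df = n−1) form clusters under the combined
relation: same electrode at adjacent samples (|Δs| = 1, no gap bridging),
or adjacent electrodes at the same sample. The cluster statistic is the
mass Σt (not size or max). The null distribution is the maximum |mass|
over per-participant sign-flip permutations, computed separately for
negative and positive clusters from the same permutations; each observed
cluster gets `p = (1 + #{null ≥ |mass|}) / (n_perm + 1)`, which is valid
and strictly positive. Sign flips only change the sign of each
participant's contribution, so per-point sums of squares are permutation
invariant — the t field for all permutations reduces to one matrix
product, and only the connected-component labelling is per-permutation.

"Most significant negative cluster" = largest |mass| among negative
clusters with p < .05; ties break by earliest onset sample, then
lexicographic electrode labels. Data-driven SPN re-extraction takes the
cluster's electrode set × its half-open sample span (a rectangular hull:
member gaps inside the hull are included, as in standard practice).

## Synthetic catalogue generator

The generator emulates stage-v condition averages, not raw EEG:

* **Waveforms.** P1 and N1 are Gaussian bumps (defaults +5 µV at 110 ms and
  −8 µV at 170 ms, 25 ms width — magnitudes in the range of observed
  posterior P1/N1 group means), shared by both conditions. The SPN is a
  raised-cosine-edged plateau (default 250–1000 ms, 50 ms edges) added to
  the regular condition only. The injected field is rescaled by the
  reciprocal of its own mean over the calibration cluster/window
  (PO7/O1/O2/PO8 × [300, 1000) ms), so in the noise-free limit the
  extracted amplitude equals the requested amplitude exactly.
* **Topography** is a Gaussian falloff (σ = 0.5 rad great-circle) from the
  nearest of PO7/O1/O2/PO8, weight 1 at those seeds; an explicit
  per-electrode weight table can be supplied instead.
* **Variability.** Experiment-level true amplitudes follow
  `0.071 − 1.669·W − 0.416·Task` plus a Normal(0, 0.75 µV) residual — the
  residual SD is calibrated so the two predictors explain roughly one
  third of amplitude variance, the level observed in grand-average SPN
  catalogues. Participant amplitudes are Normal(true, 1.6 µV). Measurement
  noise is iid Gaussian per sample and electrode with SD
  `noise_sd/√n_trials` (defaults 1.0 µV, 60 trials); an AR(1) option
  exists but defaults off. Epochs are baseline corrected after noise, as
  real pipelines do.
* **Publication rule.** P(published) is logistic in the true amplitude
  (centre −0.95 µV, slope 2 per µV), so stronger (more negative) SPNs are
  likelier to be "published" — the file-drawer mechanism the bias stage is
  meant to detect.
* **Seeding.** One root seed; experiment streams come from
  `SeedSequence.spawn` children, so subsetting a catalogue never changes
  the experiments that remain.

What the generator does *not* emulate: 1/f spectra, ocular/muscle
artifacts, temporal autocorrelation (by default), electrode-specific noise,
trial-level structure. Tests passing on synthetic catalogues therefore
establish the *statistical machinery* (estimator consistency, test
validity, recovery of planted structure), not robustness to real-world EEG
pathologies.

## Problem sizes in the test suite

The suite verifies stochastic properties at sizes chosen to balance
statistical resolution against a desk-scale run: power solver vs
Monte-Carlo on a 4 × 4 (d, n) grid at 10⁵ replicates per cell (tolerance
0.005); permutation-test type-I rate over 200 null datasets (n = 12, 16
electrodes, 282 samples, 500 permutations) against binomial 99% bounds;
DerSimonian–Laird CI coverage over 500 simulated meta-analyses (k = 12,
accepted band 92–98%); generator parameter recovery on 40-experiment
catalogues over a 16-electrode posterior montage. Planted-signal recovery
uses a sharp-edged plateau across a connected posterior montage including
the midline (Pz/POz/Oz/Iz) — with signal confined to disconnected
hemisphere components the test would, correctly, find two clusters.

## Known limitations

* The quadratic effect-size model is descriptive; extrapolation outside
  the fitted amplitude range warns but does not refuse.
* Between-subject designs, TFCE, frequency-domain clustering and a priori
  ANOVA power for >2 conditions are out of scope.
* The bundled montage mirrors the standard Biosemi-64 naming; labs with
  other caps should supply a position table.
* Egger's intercept test and DL pooling both behave poorly at very small
  k; the implementations require k ≥ 3 and k ≥ 1 respectively but small-k
  output should be read descriptively.
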