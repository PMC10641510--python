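# Methods

This note documents the models, defaults and numerical choices behind
`nirsnet`, and what the synthetic validation does and does not establish
about real recordings.

## Synthetic cohort generator

The generator (`nirsnet.simcohort`) emulates a two-condition pediatric
fNIRS session: a 12-min resting state and a 12-min passive story-listening
task with 18 stimulus blocks of ~20 s and inter-stimulus intervals drawn
uniformly from 15–20 s. Defaults follow the recording conditions the
pipeline targets: 50 measurement channels, wavelengths 760/850 nm,
sampling rate 7.8 Hz, 720 s per condition, cohorts of 13 patients and 26
controls with ages uniform on 6–18 years.

**Forward model.** Clean oxy-hemoglobin dynamics are the sum of

* a task-evoked component: a canonical double-gamma HRF (peak ≈ 6 s,
  undershoot ≈ 16 s, unit peak after convolution with the block design)
  scaled by `evoked_amp_uM` (default 0.5 µM — a modest cortical response);
* endogenous fluctuations: a multivariate normal with a planted
  channel-by-channel correlation matrix, scaled to `hemo_sd_uM` (1 µM) and
  smoothed by a Gaussian kernel of width 0.5 s shared across channels.
  Identical per-channel filtering rescales all covariances equally, so the
  planted correlation matrix is preserved exactly in population. The
  kernel width trades realism (true hemodynamics are slower) against the
  effective sample size available to a 720-s recording; 0.5 s keeps the
  bootstrap estimator's sampling SD below 0.05 while staying inside the
  0.001–0.5 Hz analysis band.

Planted correlation structure: within-hemisphere 0.35, cross-hemisphere
0.15, +0.10 within-hemisphere during the task; patient cohorts apply a
left-intra-hemispheric decrement (−0.08) and right increment (+0.04), and
age drifts edge coupling by +0.01/year in Fisher-z space. Arbitrary edge
overrides are repaired to the nearest positive-definite correlation matrix
(eigenvalue clipping + re-standardization). The evoked response adds a
rank-one term to the covariance; the *implied* total correlation of the
clean component is computed analytically and stored as ground truth, so
convergence tests compare against the true generative value, not the
nominal block value.

ΔHbR is modelled as −0.4 × ΔHbO: sufficient for testing the two-wavelength
algebra, not a physiological venous model. Concentrations map to optical
density through the modified Beer–Lambert law (see below), and nuisances
are added in OD space: a shared cardiac sinusoid with a per-subject rate in
0.9–1.6 Hz and small per-channel amplitude/phase jitter (amplitude
4·10⁻³ OD), three slow sinusoids per channel emulating 1/f drift
(2·10⁻³ OD), and white noise (10⁻³ OD). Poorly coupled channels carry 2 %
of the cardiac amplitude and 8× the noise. Raw intensity is
`I0·10^(−ΔOD)`.

**Motion artifacts** (spike = flat-topped Tukey transient, step = boxcar,
drift = ramp) are injected with amplitudes expressed in units of the
robust SD of the moving-average deviation of the OD signal — the same
statistic the detector thresholds. Because a 6-s moving average tracks
into events of comparable duration (attenuating the deviation 3–5×),
events that are meant to satisfy the 3-SD/3-s detection rule are injected
at 15–25 SD nominal amplitude, which is typical of real motion in raw
fNIRS. Slow drifts deliberately do not satisfy the rule and are handled by
the band-pass filter instead.

**Statistics-level fast path.** `generate_cohort(..., signals=False)`
draws a standardized network metric per subject and a cognitive score from
`score = 100 + slope_g·metric + N(0, 3)` with group-specific slopes
(default −1.4 for patients, 0 for controls) without synthesizing
recordings. This is what the moderation calibration uses (200 cohorts);
the full-signal path is exercised by the pipeline tests. The planted
slopes live in the generative direction (score given metric); the
moderation model is generic in (outcome, predictor) so the planted
coefficients are directly the estimands.

**What the generator does not emulate:** spatially continuous sensitivity
profiles (channels are exchangeable except for hemisphere labels),
non-stationary arousal, respiration (only cardiac and drift bands),
HbR-specific physiology, and realistic artifact morphology beyond the
three canonical shapes. Passing tests therefore validate the *estimators*
under the stated generative assumptions, not the physiological fidelity of
any particular clinical dataset.

## Preprocessing

* **Cardiac-coherence QC** — Welch cross-spectra (Hann, 256-sample
  segments, 50 % overlap) of the wavelength-averaged ΔOD; the cardiac peak
  is the maximum of the channel-median PSD in 0.8–2.3 Hz; channels whose
  median magnitude-squared coherence with all others at that frequency
  falls below 0.1 are excluded. The coherence estimate has a bias floor of
  ≈ 1/(number of segments); at 720 s (~42 segments) the floor is ≈ 0.02,
  comfortably below the threshold, but recordings under ~2 minutes cannot
  support this QC and raise instead.
* **Artifact detection** — deviation from the 6-s moving average
  thresholded at 3 robust SD (1.4826 × MAD of the deviation over the whole
  record, so artifacts do not inflate their own threshold); per-channel
  runs > 3 s (sub-0.5-s gaps closed) on ≥ 5 % of channels become events;
  channels correlating > 0.8 with the flagged channels' mean segment join
  the event; events < 2 s apart merge.
* **PARAFAC correction** — the interval ±4 s context is decomposed
  (time × channel × wavelength) by CP-ALS; rank starts at 1 and grows to at
  most 3 while a component adds ≥ 1 % explained variance. The segment
  baseline is taken from context samples only, so the artifact's own mean
  cannot leak into it. Components whose within-interval time-course
  variance exceeds 2× their context variance are subtracted inside the
  interval with a 1-s linear cross-fade at each boundary. Non-convergence
  or no dominating component leaves the interval for exclusion.
* **Masking** — seizure-labelled intervals, artifacts > 10 s, and failed
  corrections are invalid. Intervals are half-open `[onset, onset+dur)` in
  seconds, converted by floor(start)/ceil(end).
* **Band-pass 0.001–0.5 Hz** — the 4th-order Butterworth magnitude is
  applied zero-phase as |H(ω)|² in the frequency domain on reflect-padded
  valid segments. Forward–backward recursion computes exactly this
  response, but with the 0.001 Hz corner at fs = 7.8 Hz the recursive
  filter's poles sit so close to the unit circle that float64 recursion
  injects percent-level broadband error; the spectral form is exact to
  machine precision. Segments are filtered independently — no
  interpolation across exclusions, so excised data cannot leak.
* **Beer–Lambert** — per channel the 2×2 system
  `ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ, age)` is solved
  exactly. Extinction coefficients are the standard compiled in-vitro
  spectra (760 nm: 5.860·10⁻⁴/1.5485·10⁻³; 850 nm:
  1.0580·10⁻³/6.9132·10⁻⁴ cm⁻¹µM⁻¹), config-overridable. DPF uses the
  published general age- and wavelength-dependent equation; source-detector
  distance defaults to 30 mm when the montage omits it.
* **Global signal regression** — OLS of each channel on (intercept, mean
  of retained channels); residuals are orthogonal to the regressor on
  valid samples.

## Connectivity

Windows are drawn uniformly over the circularized record (overlapping
draws allowed); a window is valid only if it contains no masked sample
(strict — no partial-overlap tolerance, so seizure data can never enter),
with a cap of 100× the requested count before erroring. Correlations are
zero-lag Pearson; flat channels yield missing pairs that are averaged over
the windows where they exist. Fisher z uses atanh with |ρ| = 1 clipped at
1−10⁻⁷ under a warning. The age GLM is fitted edge-wise by OLS pooled over
patients and controls per condition; stage B subtracts `β̂1·(age − mean
age)`, retaining the grand level because the downstream absolute
thresholds need the FC scale, not zero-mean residuals (raw residuals via
`regress_age(..., keep_level=False)`). With degenerate
(equal) ages stage B equals the input, with a warning.

## Network metrics

Thresholds apply by default directly to stage-B values (Fisher-z scale);
`threshold_graph(..., scale="r")` back-transforms to correlations first
for users who prefer thresholding on the r scale. Edge weights are |z|;
path lengths are 1/w (the standard convention for correlation-weighted
graphs); λ is the mean finite shortest path over ordered pairs, E_global
the mean of 1/d with disconnected pairs contributing 0, E_local the global
efficiency of each node's neighborhood subgraph, and γ the geometric-mean
(Onnela) weighted clustering with weights scaled by the graph maximum.
E_global is *not* algebraically 1/λ for weighted graphs; both are
reported. Hemispheric γ/E_local are means of nodal values over each
hemisphere's channels computed on the full graph, preserving
cross-hemispheric neighborhoods (a hemisphere-subgraph mode is available
via `weighted_metrics(..., hemisphere_subgraphs=True)`). All-pairs distances use vectorized
Floyd–Warshall (n ≤ 50 nodes).

Null models are Maslov–Sneppen degree-preserving double-edge swaps (10
attempted swaps per edge) on the binary structure with the original weight
multiset reassigned uniformly at random. `M_rand` is the mean of each
metric pooled over the 100 null graphs of every subject of a group;
per-subject normalization is available via the `groups` argument
(one group per subject). σ = γ_norm/λ_norm uses whole-graph γ.

The validated sparsity range is the largest contiguous sub-grid of
[0.01, 0.17] on which the cohort-mean minimal binary degree is ≥ 1 and the
mean normalized γ and λ both exceed 1 (for small networks the γ criterion
γ > γ_rand is the same inequality). AUC is the trapezoidal integral over
the validated grid; metrics valid at fewer than two grid points yield a
missing AUC.

## Statistics

Permutation tests use the pooled-variance Student t, with one permutation
sequence shared across all edges to preserve the null's cross-edge
dependence, and the add-one convention `p = (#{|t*| ≥ |t|} + 1)/(B + 1)`.
When the number of distinct group splits is ≤ B the test switches to exact
enumeration (p = count/splits, the observed split included). Edge-wise
results are reported uncorrected at α = 0.05; an FDR option exists but is
off by default. Group coding is control = 0, patients = 1; the moderation
predictor is centered on the pooled mean, so β1 is the control simple
slope and β1+β3 the patient slope (SE from the coefficient covariance,
df = n−4). Partial η² uses type-III (drop-one) sums of squares. Clinical
factors are coded FLE = 0/TLE = 1, left = 0/right = 1/bilateral = 2,
seizure control yes = 1/no = 0 for Spearman correlations; numeric factors
use Pearson. Handedness is excluded from group tests.

## Determinism and problem sizes

Every stochastic stage takes a seed; the pipeline derives per-stage seeds
from the master seed and stage name (all < 2³¹), so a full run is
bit-reproducible from its config. The validation suite uses the study's
native sizes where they are cheap (720-s records, 200×60-s bootstrap,
2,000 permutations, 100 null graphs, 200 simulated cohorts) and scales the
end-to-end pipeline smoke down (3+3 subjects, 180-s records, 20 windows,
5 null graphs) since it exercises plumbing, not estimator precision.

## Known limitations

* PARAFAC correction assumes artifacts are low-rank across
  channel × wavelength; spatially focal artifacts on a single channel are
  below the 5 %-of-channels detection rule by design and are left to the
  band-pass filter and robust statistics downstream.
* The moving-average detector cannot see events whose deviation statistic
  stays under 3 SD (e.g., slow drifts or long low-amplitude steps); this
  mirrors its specification rather than a bug.
* Coherence QC needs ≥ ~2 minutes of data before the coherence bias floor
  clears the threshold.
* The z-scale thresholding and the group-pooled `M_rand` convention are
  reasonable defaults but not the only defensible choices; both have
  config switches.
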