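# Methods

`smfkit` implements a complete serum-metabolic-fingerprint (SMF) diagnostic
workflow for nanoparticle-assisted LDI mass spectrometry: synthetic cohort
generation, spectrum QC, preprocessing into an aligned fingerprint matrix, a
five-model classifier bank with repeated cross-validation and DeLong
inference, integrated-gradients biomarker-panel selection, metabolite-pattern
stratification of cases, and FDR-constrained average-power analysis.  This
note records the models, the defaults and why they were chosen, and the
limits of what the synthetic experiments demonstrate.

## Synthetic cohort model (`smfkit.synthgen`)

A cohort is a case/control design (default 144/144, the scale of the
emulated study) measured five times per sample on a dense low-mass grid
(m/z 100–600, 124,000 raw points).  One acquisition is

* a sum of Gaussian peaks (sigma 0.02 Da — narrow relative to the 0.05 Da
  analysis bin) at 134 positions drawn uniformly with a 0.5 Da minimum gap;
* per-sample apex heights `h_ij = b_j · exp(sigma_log · z)` — log-normal
  biological variation so fold changes act multiplicatively;
* a smooth exponentially decaying chemical baseline (amplitude 20,
  length-scale 150 Da);
* heteroscedastic detector noise, sd = `noise_cv`·(local clean signal) plus
  an additive floor, together with one multiplicative per-replicate scale
  factor `exp(N(0, noise_cv))` — this makes technical replicate CVs land
  near `noise_cv` (5% → CV 3–7%), matching QC practice;
* one m/z calibration shift per spectrum, `N(0, 0.01 Da)`;
* one multiplicative scale factor per batch (sd 5%), so batch-stability QC
  has something to detect; and
* one standard-serum QC acquisition per batch sharing a fixed height vector.

Differential structure: `n_differential` peaks (default 27 — one fifth of
the signals, mirroring the fraction that carries model attributions in
fingerprint studies) are scaled by `2^log2fc` in cases, with |log2FC| drawn
from 0.6–2.8 and every third planted peak down-regulated (a 6-peak design
gives the 4-up/2-down pattern typical of reported panels).

**Calibration of `height_sigma_log` (default 1.4).**  The biological spread
sets the discriminative value of a single peak: a feature with fold change
FC and log-normal spread sigma has a univariate AUC of
`Phi(FC·ln2 / (sigma·sqrt(2)))`.  Published fingerprint panels report single
metabolite AUCs of roughly 0.68–0.84 at |log2FC| ≈ 1.9–2.8; sigma_log = 1.4
reproduces exactly that band (0.75–0.84) and puts the all-signal Bayes
ceiling near 0.97 — the regime in which a trained model can reach AUC ≈ 0.95
but no model saturates at 1.0.  Smaller spreads (e.g. 0.4) make every
classifier trivially perfect and void any model comparison.

The generator is deterministic given `seed`, and its ground truth
(peak positions, differential subset and signed log2FC, pi0 = 1 −
n_differential/n_peaks, optional case-cluster labels, noiseless per-sample
heights) is returned alongside the spectra so every downstream stage can be
scored exactly.  `cohort_feature_matrix` applies the identical statistical
model but skips spectrum rendering, for studies of the downstream stages at
scale.

What the generator does **not** model: adduct species and isotope patterns,
detector saturation, correlated metabolite modules, retention of chemical
noise peaks, and non-multiplicative batch distortions.  Consequently,
passing recovery tests show the pipeline is correct under the stated
statistical model — not that it is robust to every artifact of real LDI-MS
data.

## Preprocessing (`smfkit.preprocess`)

Chain: Gaussian smoothing (sigma = 1 grid point, reflect-padded, conserves
total intensity) → summation binning onto half-open 0.05 Da bins (conserves
in-range intensity exactly) → white top-hat baseline removal (signal minus
its morphological opening; flat element 2.0 Da = 40 bins, far wider than a
peak and far narrower than baseline undulation; idempotent and nonnegative)
→ local-maximum peak detection → single-linkage m/z alignment →
replicate averaging.

Peak detection gates strict local maxima (±2 bins, leftmost apex on
plateaus) at S/N ≥ 3.  The noise scale is 1.4826 × MAD of the
baseline-corrected spectrum, estimated **locally** in 500-bin windows:
detector noise scales with the underlying signal, so bins under the low-mass
baseline are several times noisier than the high-mass tail and a single
global MAD either floods the low-mass region with false peaks or misses real
ones elsewhere.  S/N is measured above the local median — the small positive
offset grey opening leaves under noise.  Apex positions are refined by an
intensity-weighted centroid over apex ± 1 bin, giving sub-bin (±0.006 Da in
practice) position accuracy.

Alignment pools all detected apexes, sorts them, and cuts wherever
consecutive positions differ by more than the tolerance (0.1 Da) — 1-D
single linkage.  A cluster becomes a signal if present in ≥ 50% of spectra
(`min_fraction`; the study-scale signal count emerges from the data rather
than being fixed).  Reference m/z is the member median; a spectrum's value
is the summed intensity of its member peaks, 0 if absent (zeros, never
missing values, so fold-change and t-test arithmetic stays total).

## Classifier bank (`smfkit.classify`, `smfkit.nn`)

Five models, hyperparameters fixed at the printed values: L2 logistic
regression (inverse strength 1/0.140), AdaBoost (60 full-depth decision
trees, learn rate 1.0 — full trees, not stumps, per the printed
"base estimator = Tree"; also consonant with AdaBoost being the weakest
model in the emulated study), kNN (k = 5, uniform, Euclidean), Gaussian
naive Bayes, and the fingerprint network.

Evaluation: repeated stratified k-fold CV (10×10 by default; suites run
10×2 on 40/40 cohorts to stay fast), with the feature scaler fit on
training folds only — a leakage canary test demonstrates the failure mode
it prevents.  AUC inference uses DeLong structural components (variance,
95% CI, and the paired two-sided test); threshold metrics (accuracy, F1,
MCC, recall, precision, specificity) are computed at probability 0.5, with
zero-denominator metrics reported as NaN rather than 0.

**Network architecture.**  Input is the z-scored fingerprint zero-padded to
144 cells (134 signals + 10 zeros).  The padded vector passes through:

1. a fixed `asinh` dynamic-range compression (gain 10, normalized to unit
   slope overall).  Raw LDI intensities are log-normal; after z-scoring
   they remain heavily right-skewed, and gradient training on such inputs
   stalls while tree ensembles (scale-invariant) do not.  A smooth
   compressive front end — the network's own first operation, exactly
   differentiable — restores the end-to-end representation-learning
   advantage that motivates using a network at all;
2. two **locally connected** 1-D layers (kernel 3, stride 1, 16 then 32
   channels, ReLU).  Locally connected means no weight sharing across
   positions: each m/z signal owns its filter bank, i.e. a learned
   per-signal nonlinear rescaling plus local context.  (A weight-shared
   convolution was tried first and underfits badly — fingerprint positions
   are not translation-invariant);
3. mean-pooling over positions into one 32-vector — an additive-model
   inductive bias that controls overfitting at n ≈ 100;
4. a bilinear interaction stage: element-wise product of two learned linear
   projections (the second initialized at 1 so training starts
   near-linear), dropout 0.25; and
5. a dense softmax head over two classes.

Training: Adam 1e-3, batch 32, 200 epochs, decoupled weight decay 1e-3,
float32, all randomness (init, shuffling, dropout) from one seeded
generator — two runs with the same seed produce bit-identical weights.  The
implementation is plain NumPy with hand-written backpropagation; the
backward pass also yields exact input-space gradients (verified against
finite differences), which integrated gradients consumes directly.

## Panel selection (`smfkit.panel`)

Integrated gradients along the straight path from an all-zeros baseline in
standardized space (the natural "absent signal" reference), midpoint
Riemann rule, 300 steps; the completeness axiom (attributions summing to
`F(x) − F(baseline)`) is recorded per sample and holds within 1% on every
tested model.  Signals are ranked by mean absolute attribution across
samples (ties broken toward ascending m/z) and the top ⌈20%⌉ retained.

The panel is the triple intersection with |log2FC| > 1.8 (group means on
raw intensities; a zero mean is replaced by half the smallest nonzero value
of that signal) and two-sided Welch p < 0.05 (no multiple-testing
correction inside the filter; BH q-values are reported alongside).  Panel
evaluation reports the cross-validated AUC on the panel columns and
orientation-corrected univariate AUCs per member.  Annotation matches panel
m/z against a user-supplied local mass table within 150 ppm after +H/+Na/+K
adduct offsets — strictly offline.

## Stratification (`smfkit.stratify`)

Case fingerprints are z-scored per signal and clustered by Ward-linkage
agglomerative clustering on Euclidean distance.  When k is not forced it is
chosen over k = 2..8 by majority vote of silhouette, Calinski–Harabasz and
the gap statistic (10 uniform reference draws, first-SE rule), with the gap
statistic breaking ties.  Phenotype association uses per-scale ranks
(completion-time scales inverted by an explicit orientation registry —
silent mis-orientation would flip the composite), summed into a rank-sum
composite; group differences are tested by Kruskal–Wallis with tie
correction (plus an exact permutation p for n ≤ 12, via multiset
enumeration), Dunn's pairwise z-tests with Bonferroni adjustment, and an
ordinal Kruskal–Wallis on VCI status (none < mild VCI < VaD).

## Power analysis (`smfkit.power`)

Model: feature statistics are N(0,1) under the null and
N(theta·sqrt(n/2), 1) under the alternative, with pi0 the null fraction and
lambda the effect-size density (theta in pooled-SD units).  Under BH control
at FDR delta, the sustainable per-test threshold u satisfies

    ∫ T(u, θ) λ(θ) dθ = u · π0 (1 − δ) / (δ (1 − π0)),

where T is the two-sided two-sample z-test power.  The solver brackets the
largest root on a log grid and bisects to 1e-8; average power is the
left-hand integral at the root.  If the constraint never binds (δ ≥ π0 in
effect) the threshold is 1 and power saturates; if no root exists, no
discoveries are sustainable and power is 0.  The solver agrees with an
independent Monte-Carlo oracle — simulate m features, run adaptive BH at
level δ/π0, record the true-positive fraction — within ±0.01 across a
(π0, θ) grid.

pi0 is estimated from p-values by the maximum-likelihood convex decreasing
density on [0,1] (EM over a mixture of triangular densities plus a uniform
component; the fitted density at p = 1 is the null proportion), with
Storey's smoothed lambda-grid estimator as a declared alternative.  lambda
is recovered by subtracting the pi0-scaled null from the statistic
histogram and deconvolving the remainder with nonnegative least squares
against the normal kernel (light second-difference penalty, 0.01); mass
inside the ±0.1 zero-exclusion window is removed (effects that small are
unmeasurable) and pi0 readjusted upward accordingly.

**Known limitation.**  Gaussian deconvolution has logarithmic convergence
rates: lambda is trustworthy only where effects are separated from the null
by at least about one standard error, and p-value-based pi0 estimators are
upward-biased when alternatives are weak.  The end-to-end pilot check
(estimate pi0 and lambda from pilot statistics, solve for the minimal n at
90% power, compare with the truth-based Monte-Carlo oracle) is therefore
validated in the resolvable regime (theta ≈ 1.5 SE), where it agrees within
20%; with weak, heavily overlapping effects any method of this family
over- or under-shoots.

## Problem sizes in the test suites

Suites exercise the full 124k-point raw grid and all 134 peaks wherever the
stage under test consumes raw spectra, but with 12–100 samples per arm and
2–3 CV repeats rather than the full 144/144 × 10-repeat design — the
statistical properties under test (recovery, calibration, ranking) are
scale-free or averaged over cohort replicates.  The model-bank ranking
check averages pooled CV AUCs over three independent default-condition
cohorts, since a single 80-sample cohort makes a qualitative ranking a
coin-flip on cohort draw.

## Degenerate inputs and tie-breaks

All-zero spectra detect zero peaks (not an error); an absent aligned peak
is 0; plateau maxima resolve leftmost; equal-rank ties average; duplicate
clustering rows report k = 1 with a degenerate flag; confusion metrics with
empty denominators are NaN; Kruskal–Wallis on all-identical values reports
H = 0, p = 1; fold change on an all-zero signal is 0; the mzML reader/writer
round-trips 64-bit float arrays bit-exactly.
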