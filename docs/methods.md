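# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic-cohort tests demonstrate.

## Signal model and preprocessing

Input is a per-participant, per-condition matrix of [oxy-Hb] concentration
change, 46 channels at 10 Hz, covering a testing phase of 20 trials (3 s
stimulus + 10 s fixation) with 2 s of baseline padding at each end
(~2640 samples per condition). The preprocessing chain is fixed in order
and strictly per-channel:

1. **HRF low-pass.** Convolution with the canonical double-gamma
   hemodynamic response function (peak delay 6 s, undershoot delay 16 s,
   unit dispersions, peak:undershoot ratio 6; 32 s support; unit-sum
   weights). The convolution is causal with reflect padding at the onset,
   chosen so that no onset transient leaks into the autoregressive fits; a
   unit-sum kernel leaves constant channels untouched. The gain at the
   cardiac band (1.2 Hz) is <0.05, so pulse components are effectively
   removed here.
2. **Detrending.** Default: regression on a constant + linear term + DCT
   cosine set containing every period longer than the 128 s cutoff
   (dropping the constant enforces ~zero channel means). The polynomial
   terms remove ramp-like drift exactly; the cosines absorb slow
   oscillatory drift. A wavelet variant decomposes each channel (db4,
   periodized) to the level whose approximation band lies below 1/cutoff Hz
   and subtracts the reconstruction of the MDL-selected coarse
   coefficients. The wavelet-based detrending used by the original
   acquisition software is not publicly specified; both methods here are
   documented drift removers behind one interface, and the DCT default is
   the reproducible choice.
3. **Baseline correction.** Per channel, the straight line through
   (center of first 2 s window, its mean) and (center of last 2 s window,
   its mean) is subtracted; both window means of the output are exactly
   zero.

Because every step is per-channel and linear, preprocessing commutes with
channel permutation, and re-running it on a preprocessed recording is
refused (provenance records each applied step).

## Pairwise Granger causality

For an ordered pair (A, B), both series are fitted with nested
least-squares models at a common order *p*: an AR(*p*) of the target with
intercept, and the same augmented with *p* lags of the other channel. With
maximum-likelihood (1/T) residual variances the magnitude

    G(B→A) = ln( σ²_reduced(A) / σ²_full(A) )

is non-negative by nesting, invariant to separate rescaling of either
channel, and asymptotically T·G ~ χ²(p) under independence (so the
small-sample null bias of a single weight is ≈ p/T). Note the published
formula in the emulated study prints the ratio the other way up, which
would be non-positive under the same nesting; since the weights are used as
magnitudes ("intensities"), the conventional Geweke orientation is the only
consistent reading and is what is implemented.

*Order selection.* One shared order per pair minimizes the bivariate VAR
BIC, `T·ln det Σ̂ + k·ln T` with k = 2(2p+1), over p = 1..p_max
(default p_max = 10, i.e. 1 s of history at 10 Hz; ties go to the smaller
order). All candidate orders are scored on the common sample
t = p_max..T−1 so they see identical data; the final magnitudes are then
computed at the selected order on its full sample t = p..T−1. The scan is
implemented with one shared cross-product (Gram) matrix per recording and
batched small solves, which keeps a 46-channel map (2070 pairs) at a few
seconds; the reported magnitudes come from the same code path as the
public `granger_pair`, which unit tests pin against an explicit
normal-equation oracle at 1e-10.

Causality is strictly bivariate (the published model), computed on the
continuous preprocessed session per condition, not per-trial epochs. A
constant or non-finite channel marks its incident edges missing (NaN) with
a warning instead of aborting the map.

## Group model per edge

With two conditions per participant, the repeated-measures ANOVA
(race within × continuous age between) reduces exactly to two ordinary
regressions on per-participant scores:

* mean score M = (own + other)/2 on centered age → **age** main effect
  (slope F);
* difference score D = own − other on centered age → **race** main effect
  (intercept F: the race difference at the cohort mean age — the
  evaluation point is a convention and is stated here because the source
  analysis leaves it implicit) and **race × age interaction** (slope F).

Each F has df (1, N−2) — which is the only reduction consistent with the
published df of 122 at N = 124 — and partial η² = F·df1/(F·df1 + df2).
D is the per-participant neural other-race effect (NORE); its Pearson
correlation with age summarizes the developmental trend of the race
difference. Tests pin the reduction against an independent stacked GLM
with participant fixed effects.

## Bootstrap-averaged effect sizes and the permutation decision

The observed statistic per effect is the mean partial η² over B subsamples
of ⌊N/2⌋ participants drawn without replacement (B defaults to 10,000 in
the library, 500 in the shipped calibration runs). Significance uses a
permutation null with the top-5% rule: an effect is significant when the
observed average strictly exceeds the empirical 95th percentile of the
null.

*Scrambling.* For the race and interaction effects, each null replicate
flips every participant's own/other labels with a fair coin — the
exchangeability-preserving scheme for paired data (it negates D and leaves
M untouched). Because participant means are invariant to condition flips,
that scheme carries no information about the age effect; the age-effect
null instead permutes ages across participants. This deviation is recorded
in the output provenance.

*Null statistic.* Two flavors are provided.

* `null_stat="averaged"` (default): each null replicate is itself a
  subsample-averaged η² (100 inner subsamples per scrambled cohort by
  default) — the null statistic matches the observed statistic, which is
  what gives the rule its nominal level. Calibration on pure-null cohorts
  (200 cohorts, N = 124, B = 500) lands at 5% ± Monte-Carlo noise; this is
  what `scripts/acceptance.py` recomputes.
* `null_stat="subsample"`: one single-subsample η² per scrambled
  replicate, which is the literal reading of the published description.
  A single subsample draw spreads more widely than an average of draws
  while sharing its mean, so comparing the observed *average* against this
  null is conservative: measured type-I is ≈1% at the nominal 5%. The
  package defaults to the matched flavor because a decision rule should
  attain its stated level; the literal flavor remains available for
  sensitivity analyses.

The permutation p-value uses the add-one estimator
(1 + #{null ≥ observed})/(1 + B) and is non-increasing in the observed
statistic by construction. No cross-edge multiplicity correction is applied
beyond this procedure (matching the emulated analysis); a Benjamini–
Hochberg pass can be applied downstream on the reported p-values if
desired.

*Post-hoc tests.* After a significant interaction: paired t (own − other)
within the younger and older groups and two-sample t (younger − older) per
condition. The age split defaults to the cohort median, since no split
rule is published.

## Network assembly

Significant edges per effect form a directed network over the montage.
Edge classes follow the probe-set blocks (channels 1–24 frontal, 25–46
occipital), giving the exact partition 552/462/528/528 of the 2070 ordered
pairs. Interaction edges are subtyped from the per-condition least-squares
slopes of weight on age — a slope is "up"/"down" only when its two-sided
p < 0.05, else "flat" (an explicit convention; the source analysis never
defines how "did not change with age" was judged) — combined with the sign
of the NORE–age correlation; sign patterns outside the four published
families are reported unclassified rather than forced. Exports (GraphML
with full montage node attributes, TSV edge lists, optional diagrams) are
byte-deterministic given identical inputs.

## Synthetic cohorts: what they emulate and what they do not

Defaults reproduce the emulated study conditions: N = 124 participants,
ages continuous on [3.25, 13.49] years (uniform by default — maximal
leverage for age-slope recovery; a truncated normal with the reported
moments, mean 7.77 / SD 2.80, is available), 46 channels at 10 Hz, 20
trials of 3 s + 10 s, 2 s padding. The neural signal is a VAR with 0.3
self-coupling per channel and planted couplings injected at lag 1
(configurable); the realized coefficient of edge i→j is
`base + age_slope·age + [own]·(cond_offset + inter_slope·age)`, and
configurations whose companion spectral radius reaches 1 for any cohort
member are rejected. Nuisance components are sinusoids at ~1.2 Hz
(cardiac, amplitude 0.3), ~0.3 Hz (respiratory, 0.5), ~0.1 Hz (Mayer,
0.8) and 0.004 Hz (slow drift, 1.5) — amplitudes relative to unit
innovation SD, ordered slow > fast as in real fNIRS — with phases and
amplitude jitter drawn per participant and shared between that
participant's two conditions. Behavioral accuracies are simulated with a
continuous age effect (slope 0.0325/year against residual SD ≈0.11, which
reproduces an age F near 90 at N = 124 in expectation), a small own-race
advantage (0.02) and no interaction.

Problem sizes in the shipped tests are the package's own choices: the
planted-recovery run uses 12 channels (132 directed edges) at the full
session length and N = 124 with five planted interaction edges
(base 0.08, inter_slope 0.02/year), and the calibration run uses
edge-level weight draws (Gamma(1.5, 0.02), the scale of session-length
null Granger weights) rather than full time series, since the decision
procedure only sees per-participant weights.

What passing these tests shows: the chain recovers planted directed,
age- and condition-dependent structure at realistic coupling magnitudes,
and its false-positive behavior matches the nominal level. What it does
not show: robustness to motion artifacts, optode decoupling,
non-stationary vigilance changes, hemodynamic variability across cortex
and age, or trial-locked evoked structure — none of which the generator
models. Two further caveats worth naming:

* **Filtering leakage at strong coupling.** Granger causality is invariant
  to common invertible filtering only at unbounded model order. With the
  HRF low-pass and a finite selected order, very strong planted couplings
  (coefficients approaching the stability boundary, weights G ≈ 0.5)
  induce small but systematic age-dependent biases on *neighbouring*
  edges of a strongly driven channel, which a condition-flip permutation
  correctly detects as real interactions of the filtered process. At
  empirically plausible weight magnitudes (G ≲ 0.1) this secondary effect
  sits below detection at N = 124. Interpret dense clusters of significant
  edges around a hub channel with this in mind.
* **The age-effect null is not the published scramble.** Condition
  scrambling is degenerate for the age effect (see above); the
  age-permutation null used instead tests the sharp null of no
  age-weight association.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `p_max` | 10 | max AR order (1 s at 10 Hz); the published analysis states only "order by BIC" |
| `cutoff_s` | 128 s | detrend high-pass cutoff period |
| `frac` | 0.5 | subsample fraction, without replacement |
| `b_boot`, `b_perm` | 10,000 | library defaults (the published counts); calibration runs use 500 |
| `b_inner` | 100 | inner subsamples per averaged-null replicate |
| `alpha` | 0.05 | top-5% rule, strict inequality at the 95th percentile |
| posthoc split | cohort median age | younger/older boundary |

Determinism: every stochastic component draws from `numpy` Generators
spawned per participant / per edge from a master `SeedSequence`, so results
are reproducible and independent of execution order.
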