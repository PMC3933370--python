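# Methods

## Signal model and pipeline assumptions

A chest recording is modelled as lung sound plus cardiac interference
plus slow instrumental disturbance. The stages are composable but the
default order is differentiation → heart-sound removal → segmentation →
feature extraction, because the envelope-based segmenter and the
moment-based features both assume the low-frequency cardiac and baseline
components are already gone.

**First-order differentiation.** `out[n] = x[n+1] − x[n]`, length
N − 1 (no zero padding; downstream stages never assume equal length with
the raw input). As a filter it has gain 2·sin(πf/fs): it nulls DC,
strongly attenuates drift, and mildly emphasises the upper audio band —
which also helps the texture features, since adventitious transients
carry more high-frequency energy than the vesicular carrier.

**Empirical mode decomposition.** Classic sifting: cubic splines through
interior maxima/minima, with two extrema mirror-extended about each edge
to suppress spline end swings. Sifting of one IMF stops when the
Cauchy-type criterion Σ(h_prev − h)²/Σh_prev² < 0.2 is met *and* the
mode property holds (extrema and zero-crossing counts differ by ≤ 1), or
after 10 iterations; decomposition stops at 12 IMFs or when the residue
has fewer than two interior extrema. Because each IMF is subtracted from
the running residue, ΣIMF + residue equals the input to floating-point
precision — this identity is asserted in the tests rather than assumed.

**Heart-sound removal.** S1/S2 energy concentrates below ~150 Hz while
breath sound extends well above, so IMFs are partitioned by spectral
centroid (power-weighted mean frequency, DC excluded) at a 150 Hz cutoff
(configurable). IMFs at/above the cutoff reconstruct the lung sound; the
rest plus the residue form the cardiac/trend estimate, returned for
inspection. If only one IMF exists nothing is separable and the input
passes through with a warning. On synthetic 50/50 lung/heart mixtures
this removes ~20 dB of 20–100 Hz cardiac power while moving the 300–900
Hz breath band by well under 1 dB.

**Cycle segmentation.** The analytic-signal envelope is smoothed by an
order-4 Butterworth low-pass at 5 Hz applied forward–backward. Zero
phase matters: transition points are read off as envelope minima, and
any group delay would bias every boundary. (A linear-phase windowed-sinc
FIR with the same −3 dB point, also run forward–backward, is available;
"FIR Butterworth" as a single filter does not exist, Butterworth designs
being IIR.) A minimum is a sign change of the discrete first derivative
(≤ 0 followed by > 0), ties broken toward the earlier index — an exact
zero of the derivative almost never occurs on sampled data. Two guards
reject ripple minima: a dip must have prominence ≥ 0.2 of the envelope's
robust range (5th–95th percentile; the raw min/max is distorted by
crackle spikes and filter edge transients), and surviving minima closer
than 0.3 s merge keeping the deeper one, since no credible breathing
phase is shorter. A recording edge counts as a boundary when it sits in
an envelope trough (≤ 40% of the robust range above the 5th percentile);
the derivative sign at a single edge sample is numerically meaningless.
Consecutive minima delimit phases; phase pairs form cycles; a trailing
unpaired phase is dropped and logged. Whether a cycle starts with
inspiration or expiration is not identifiable from the envelope alone,
so cycles are phase-agnostic — as are all the features.

## Features

All moments are population (1/N) moments, matching the expectation
operator in the definitions; no small-sample bias correction.

**Lacunarity.** Lung sound is signed, but box masses must be
nonnegative: samples pass through |x| by default (x² available). Box
masses are sums over all L − l + 1 stride-1 windows; ζ(l) =
mean(b²)/mean(b)² ≥ 1 by Jensen's inequality, with equality only for
constant masses. The default sweep is dyadic l ∈ {2, 4, …} capped at
min(L/4, 256) samples (32 ms at 8 kHz): boxes at the scale of
adventitious events measure their texture, while much longer boxes
mostly measure the breathing-cycle amplitude modulation that both
classes share. The scalar summary is the geometric mean of ζ(l) over the
sweep; the full (l, ζ(l)) profile is retained.

**Sample entropy.** m = 2 and r = 0.2·SD by default (the standard
parameterisation; both configurable, and r can be absolute). Templates
are restricted to the first N − m start points so the m- and
(m+1)-dimensional counts use the same template set; self-matches are
excluded; distance is Chebyshev. If either count is zero the value is
undefined and reported as an error with the counts, never as 0. For a
whole cycle (~20 000 samples at 8 kHz) the O(N²) count is prohibitive
and *resampling is not an option* — an anti-alias low-pass below the
breath band would erase exactly the fast structure the feature measures.
Instead the per-cycle value is the mean of SampEn over up to 4
contiguous 1500-sample windows evenly spaced across the cycle, at the
native rate. Deterministic, bounded cost, and the windows sample
inspiration, both transitions and expiration.

**Feature sets.** set 1 = (χ, ξ); set 2 adds ζ; set 3 adds α. Features
are computed on the enhanced signal, per cycle. A zero-variance cycle is
skipped with a warning rather than failing the recording.

## Classifiers

Both use RBF geometry, so features are standardised (zero mean, unit
variance, statistics from the training folds only) before either.
Labels are encoded +1 = abnormal, −1 = normal; a zero score breaks
toward abnormal (the conservative direction for a screening tool).

**ELM.** 10 hidden nodes by default. The center/width sampling law is a
design choice: centers uniform over the training bounding box, widths
u/(d_med)² with u ~ U(0, 1] and d_med the median pairwise training
distance, so activations are non-degenerate at the data's own scale and
depend only on the seed and order-invariant statistics (training-set
reordering cannot change the model). Output weights are the minimum-norm
least-squares solution via SVD pseudoinverse with singular values below
10⁻¹⁰·σ_max discarded; with N = Ñ and a full-rank hidden matrix this
reproduces the targets exactly.

**SVM.** The soft-margin dual with K(y, y′) = exp(−γ‖y − y′‖²)
(a Mercer kernel), box constraint 0 ≤ αⱼ ≤ C and Σαⱼdⱼ = 0, is solved by
libsvm via scikit-learn behind this package's model surface; the model
object exposes support vectors, dual coefficients αⱼdⱼ, bias and
training slack values. Defaults C = 1 and γ = 1/(d·var), both
configurable. The tests verify the dual objective against an independent
sequential-quadratic-programming solve and the decision values against a
direct kernel-sum evaluation.

## Evaluation

CA, SEN and SPE are computed per fold from the confusion counts
(abnormal positive) and averaged as percentages over the 5 folds;
pooled-count metrics over the union of test folds are also emitted. A
zero-denominator metric is reported as undefined, not 0. The default
split stratifies *cycles* by class; cycles of one subject can then
appear on both sides of a fold boundary, which is optimistic whenever
subjects differ systematically. A `subject_grouped` mode keeps each
subject's cycles in a single fold and is recommended whenever subject
identifiers exist. One seed drives generation, the fold shuffle and the
ELM hidden layer, making a whole simulate→extract→evaluate chain
reproducible byte for byte.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the pipeline relies
on, not airway physics:

- **Breath carrier**: Gaussian noise band-passed to 150–450 Hz (normal
  vesicular energy concentrates below ~500 Hz), amplitude-modulated by
  raised-cosine phase envelopes over a 0.25 floor (breath sound never
  falls fully silent within a cycle), expiration at half the
  inspiratory amplitude, phase durations 1.2 s/1.8 s with 0.1 s jitter.
  The carrier's own slow envelope fluctuations are divided out
  (smoothed-Hilbert normalisation, gain capped at 2×) so the recording's
  envelope tracks the deterministic breathing modulation the way real
  flow-locked breath intensity does — raw narrowband noise would
  otherwise contribute spurious sub-5 Hz envelope dips of its own.
- **Crackles**: exponentially damped 600 Hz sinusoids of 10 ms,
  Poisson-placed within inspirations at 15 per cycle and ~5× carrier
  RMS — a fine-crackle shower. They drive χ, ξ and ζ upward.
- **Wheezes**: 400 Hz tones ≥ 0.25 s with probability 0.3 per cycle at
  0.4× carrier RMS.
- **Turbulent-flow noise**: envelope-modulated broadband noise at
  500–1500 Hz, 0.15× carrier RMS, abnormal class only. This is the
  component that raises sample entropy: isolated deterministic bursts
  (crackles) are locally *regular* and by inflating the SD-relative
  tolerance can even lower SampEn, whereas the harsher stochastic
  high-frequency content of obstructed-airway breathing genuinely
  increases waveform irregularity.
- **Heart sounds**: S1 (35 Hz, 120 ms) and S2 (50 Hz, 80 ms) damped
  bursts 0.3 s apart at a 1.0 s beat period with 50 ms jitter, mixed so
  the clean lung-sound energy fraction equals `mix_ratio_ls` exactly.
- A single `severity` scalar multiplies crackle rate and wheeze
  amplitude so tests can sweep difficulty; `generate_abnormal` with no
  crackles and no wheezes configured degenerates to the normal
  generator's output, relabelled.

At these defaults the classes separate with large effect sizes (Cohen's
d ≳ 2 for ζ, ≳ 5 for α on first-differenced cycles) and cross-validated
accuracy saturates at 100%. Passing tests therefore demonstrate that the
chain — denoising, segmentation, features, classifiers, validation — is
implemented correctly and preserves a real class signal; they do not
predict clinical accuracy, where inter-subject variability, sensor
placement, ambient noise and disease heterogeneity are far harsher than
this generator.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale cohorts chosen as
representative defaults: a 120-cycle cohort (10 normal + 20 abnormal
recordings, 4 cycles each) for end-to-end evaluation, 100 cycles per
class for effect sizes, 200 recordings for boundary recovery, 100 random
series for feature-oracle equivalence, and 512-sample signals for the
EMD reconstruction sweep. WAV quantisation divides by 32768 on read and
multiplies by 32768 (round half away from zero, +1.0 clamped to 32767)
on write, making read→write lossless for any 16-bit source. Known
degenerate inputs: zero-variance series (moments, SampEn with relative
r) and all-zero box masses (lacunarity) raise errors naming the cause;
SampEn with no template matches reports both counts.

## Known limitations

- The heart-sound/lung-sound IMF partition by a fixed spectral-centroid
  cutoff is a deliberate, simple criterion; heavily overlapped spectra
  (loud low wheezes) would defeat it.
- Cycle detection assumes the envelope dips at phase boundaries; highly
  irregular breathing or continuous loud wheezes flatten those dips.
- The cycle-stratified CV default mirrors pooled-cycle evaluation and is
  optimistic under subject effects; use `subject_grouped` for honest
  generalisation estimates.
- Inspiration/expiration are not labelled; features treating the two
  phases separately are out of scope.
- Squawks are not synthesised explicitly; acoustically they are covered
  by the crackle + wheeze combination.
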