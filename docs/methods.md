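# Methods

## Channel selection model

Each EEG channel is treated as a sample from an amplitude distribution;
its Shannon entropy is estimated by binning the samples into `n_bins`
uniform-width bins and evaluating −Σ pᵢ log₂ pᵢ (0·log₂0 := 0), giving a
value in [0, log₂ n_bins] bits. The entropy-difference (EnD) statistic
of a channel is the absolute difference between the entropies of the two
class-specific training pools, where a class pool is the concatenation
of that channel's samples over all training subjects of the class.
Channels are ranked by descending EnD and the top N retained; the
entropy-only baseline ranks by the entropy of the two-class pooled
samples. Both rankings are always computed from training units only and
applied unchanged to test units.

Assumptions: the class effect expresses itself in the marginal amplitude
distribution of at least some channels; channels are comparable across
subjects after montage normalization (the old 10-20 labels T3/T4/T5/T6
are mapped to T7/T8/P7/P8); no filtering, re-referencing or artifact
removal is applied — the statistic sees the recordings as stored.

## Key parameters

| parameter | default | units | rationale |
|-----------|---------|-------|-----------|
| `n_bins` | 256 | bins | ≈ 8-bit amplitude quantization, a common EEG convention; keeps entropies well inside [0, 8] bits |
| `range_policy` | pooled-min-max | — | see below |
| top N channels | 3 | channels | classification accuracy plateaus after the first three ranked channels |
| window | 2048 | samples | 16 s at 128 Hz; long enough for stable histograms and decompositions |
| DWT | db4, 3 levels, periodization | — | db4 balances time/frequency resolution; periodization makes the subband energies sum exactly to the segment energy |
| EMD | 3 IMFs, Cauchy tol 0.2, ≤100 sifts | — | standard sifting configuration; deeper IMFs of 16 s windows carry little discriminative energy |
| SLBP | L = 4 | samples | gives the 31-value code alphabet 2·(2⁴−1)+1 |
| chi-square | 10 equal-width bins, keep score > median | — | retains half the features without committing to an arbitrary α |
| classifiers | k-NN k=1; SVM RBF C=1 γ=scale; 100 bagged trees | — | documented fixed defaults, all overridable |

**Binning range policy.** With `pooled-min-max` (default) the two class
pools of a channel share bin edges spanning the union of both pools, so
the two entropies are measured on a common amplitude grid: a pure
variance difference between classes then shifts the entropies apart and
is detected. With `per-signal-min-max` each pool is binned over its own
range, making the entropy scale-invariant — a deliberate
normalization-free variant, but blind to variance effects by
construction; it remains available via configuration. Standalone
single-vector entropies (including the subband/IMF entropy features) are
always binned over the vector's own range, as there is nothing to pool.

**SLBP weighting.** The left neighbourhood of a sample uses binary
weights 2^(L−1−m) (m = 0..L−1) and the right uses 2^m, a mirrored
("symmetric") scheme: a pattern and its time-reversal exchange the two
partial sums, and since the code is their sum the code histogram is
exactly invariant to time reversal. A constant-weight right-hand side
could not produce the 31-value alphabet. Codes are computed only at
interior samples with complete ±L neighbourhoods (no padding), so a
window of W samples contributes W − 2L codes; the histogram keeps raw
counts, since all windows share W. Codes are invariant to adding a
constant and to positive rescaling of the signal — consequently SLBP is
by design insensitive to pure amplitude-scale class effects.

## Empirical mode decomposition

Sifting uses cubic-spline upper/lower envelopes through the local
maxima/minima, with the two outermost extrema mirrored beyond each end
to suppress boundary divergence, and the Cauchy stopping criterion
Σ(h_prev − h)²/Σh_prev² < 0.2 (≤ 100 iterations per IMF). Extraction
stops early when the running residue has fewer than two maxima or two
minima (monotonic or constant); the remaining IMFs are zero vectors and
the result carries a degenerate-input flag. The residue is recomputed as
`signal − Σ IMFs`, so reconstruction additivity holds to floating-point
rounding on every input.

## Feature statistics

Each subband/IMF is summarized by Shannon entropy (same histogram
machinery, own range), arithmetic mean, population variance (divide by
n; fixed for determinism — at n = 2048 the ddof distinction is
negligible), and energy (sum of squares). Per channel this gives 16 DWT,
12 EMD, or 31 SLBP features; k selected channels concatenate to 16k /
12k / 31k columns, each prefixed by its channel name.

## Validation schemes

Three strategies, at subject (default) or segment granularity:
chronological 70:30 (first 70 % of units train), ten seeded stratified
random 70:30 splits with metrics averaged over repeats, and stratified
10-fold cross-validation aggregated over pooled confusion counts (fixed
rather than mean-of-fold-accuracies for determinism). Subject
granularity is the default because segment-level splits of the same
subject on both sides leak subject identity; segment granularity is
provided for comparability, with the chronological variant splitting
each recording's own timeline. Sensitivity is the ADHD true-positive
rate and specificity the control true-negative rate; an undefined
component (single-class test side) is reported as NaN with a warning,
never silently as zero.

## Synthetic cohorts

The generator emulates a two-class cohort of multi-channel recordings:
per subject, each channel is an independent stationary Gaussian AR(1)
process (lag-one coefficient 0.9, marginal SD `base_noise_sd`), with a
random per-subject gain in [0.9, 1.1]. Scalp EEG at 128 Hz is strongly
autocorrelated, and the smooth base is also what gives local-pattern
features traction: for i.i.d. samples the rank ordering within any
window is distribution-free, so no purely marginal amplitude effect
could ever register in an order-based descriptor such as SLBP. A chosen
subset of "informative" channels carries the class effect in the ADHD
group only: `variance-scale` multiplies the amplitude by
1 + effect_size; `uniform-vs-gaussian` replaces samples by
variance-matched i.i.d. uniform draws with probability
effect_size/(1 + effect_size); `bimodal-mixture` adds an i.i.d. ±delta
offset with delta = effect_size·base_noise_sd/2. All three reduce to
the null at effect_size 0. Defaults describe the desk-scale study used
throughout the tests: 20 subjects per class, the 19-electrode 10-20
montage, 64 s at 128 Hz (four 2048-sample windows per channel), three
informative channels, variance-scale effect 4.

What the generator does **not** emulate: rhythmic band structure
(alpha/theta), artifacts, volume-conduction correlation between
channels, and within-class heterogeneity beyond the gain factor.
Passing tests therefore demonstrate that the pipeline recovers injected
amplitude-distribution effects under realistic autocorrelation and
subject-level splitting — not that any particular accuracy will be
attained on clinical recordings.

## Numerical and design choices

- Histogram binning uses half-open bins with the maximum included in the
  last bin; a constant signal (degenerate range) has entropy exactly 0.
- Ranking ties (equal EnD or equal pooled entropy) keep the montage
  order of the input table — deterministic and reportable.
- Chi-square scoring drops bins with zero row total; a constant feature
  scores 0. When every feature scores at the median (all-equal), the
  median rule keeps everything rather than nothing.
- The chronological-split cut index is ⌊0.7·n⌋; simulated cohorts
  interleave the two classes so both sides of the cut contain both.
- EDF files are read as physical (calibrated) values via `mne`; the
  matrix-text dialect round-trips float64 exactly (`%.17g`).
- A single pipeline seed drives cohort simulation, split shuffling and
  ensemble randomness; rankings and feature tables are bit-reproducible
  across reruns.

Problem sizes in the test suite and acceptance script (channel-recovery
runs over 50–100 simulated cohorts, accuracy comparisons over 15–20,
EMD checks on 512-sample windows) are the package's chosen desk-scale
study conditions; all statistics are computed fresh at run time.

## Known limitations

- The number of channels to retain (N) is a manual choice.
- The EnD statistic sees only marginal amplitude distributions; purely
  spectral or cross-channel class effects are invisible to it.
- Chi-square selection assumes features are meaningfully binned on their
  training range; heavy-tailed features may occupy few bins.
- EMD on short or near-monotonic windows degrades gracefully (zero IMFs,
  degenerate flag) but carries no discriminative information there.
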