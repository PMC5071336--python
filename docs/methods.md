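# Methods

This note documents the models and procedures implemented in `usvsyntax`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Acoustic stage

**Sonogram.** The short-time power spectrum uses 256-sample blocks with
half overlap (at 250 kHz sampling: 976.5625 Hz bins, 0.512 ms frame step),
one-sided `spectrum` scaling, frames timestamped at block centers. The
default analysis window is rectangular (`boxcar`), selectable per config
(`hann` available). Rationale: the package's spectral-purity statistic is
defined as per-frame peak power over total in-band power, whose pure-tone
limit of exactly 1 only holds when a bin-centered tone concentrates in a
single bin; a Hann window leaks ~1/3 of mainlobe power into the adjacent
bins and caps the statistic near 2/3. The rectangular window's higher
sidelobes are immaterial at the SNRs where syllables are detectable at all.

**Noise thresholding.** The noise floor is estimated from all in-band
spectrogram cells as `median + k·MAD`, default `k = 15`; cells below it
are zeroed, and the threshold is recorded on the output. A *global*
estimate (rather than per frequency row) is used because a long tone makes
its own row's median equal the signal level, which would zero signal
cells; pooling rows keeps the estimate noise-dominated as long as
syllables occupy a minority of the time–frequency plane. The factor is
large because syllable detection treats a frame as voiced if *any* in-band
cell survives: with ~90 in-band bins, a per-cell false-survival rate of
even 0.5% would mark ~40% of pure-noise frames voiced, whereas `k = 15`
drives the per-cell rate to ~10⁻⁶ while tonal syllables at the SNRs of
interest exceed the floor by more than three orders of magnitude.

**Detection.** Voiced runs separated by < 10 ms of silence are merged
(exactly 10 ms separates); merged runs shorter than 3 ms are discarded.
Because an analysis block straddles its frame center, frames that barely
overlap a sound are voiced and raw run edges overshoot the physical
boundaries by up to ~1.2 frame steps; run edges whose frame power is below
`edge_trim_fraction` (default 0.1) of the run's median frame power are
therefore trimmed, after which boundaries land within one frame step of
the ground truth on synthetic audio. Intervals are half-open
`[onset, offset)` in seconds.

**Classification.** The pitch track is the per-frame argmax of surviving
in-band power; frames with no surviving power are missing. A pitch jump is
a change of ≥ 10 kHz (`pitch_jump_min_khz`) between consecutive defined
frames; runs of up to 3 missing frames are bridged (jumps in USVs often
co-occur with brief amplitude dips), longer gaps split the syllable into
notes with no jump scored across them. The 10 kHz default exceeds the
per-frame drift of frequency sweeps by an order of magnitude while
catching octave-like jumps. Labels follow the jump count (0 → `s`, one up
→ `u`, one down → `d`, ≥ 2 → `m`); syllables with under half their frames
defined, or spectral purity below 0.1 (broadband mechanical noise), are
`unclassified` and removed from all downstream analyses.

**Features.** Spectral purity and peak power are read from the unmasked
band-limited spectrum (thresholding would otherwise delete the noise
denominator and inflate purity). Amplitude is mean in-band power in dB
relative to full scale of the input waveform; frequency modulation and
bandwidth are both the span (max − min) of the pitch track, the simplest
definition consistent with the feature list.

## Sequence stage

A silence of ≥ 250 ms ends a song bout (a gap exactly at the threshold
splits). Unclassified syllables are deleted *before* gap computation, so a
removed event's span counts toward the gap it leaves; whether such an
event could bridge an otherwise bout-breaking silence is ambiguous in
principle and this convention is the recorded choice. Bouts of length 1–2
participate in counts, rates, lengths and transition analysis; they are
excluded only from the complex/simple ratio (numerator: bouts with ≥ 2
`m`; denominator: bouts with ≤ 1 `m`; among bouts of ≥ 3 syllables;
denominator 0 → NaN, not an exception). The inter-syllable-interval
distribution is reported descriptively on log-spaced bins; the fixed
250 ms threshold is authoritative for segmentation. Rate–length
association uses Spearman's correlation with mid-ranks.

## Syntax statistics

**States and counts.** States are {s, d, u, m, X} with X = silence; each
bout contributes L + 1 transitions (X→first, internal, last→X); X→X is
structurally excluded, leaving 24 transition types. Conditional
probabilities are row-normalized counts; a row whose start state never
occurs is undefined (NaN) and excluded cellwise from group means.

**Local tests.** Per transition type, per-animal probabilities are
compared with two-sided rank tests: Wilcoxon signed-rank for paired
context comparisons within a group (zero differences dropped — Wilcoxon's
original treatment), Wilcoxon–Mann–Whitney for independent groups within a
context. Exact enumeration (all 2ⁿ sign patterns, or all label
assignments, on mid-ranks so ties are handled) is used up to 12 effective
values; beyond that a normal approximation with tie correction and 0.5
continuity correction. Two-sided p = min(1, 2·min(P(T ≤ t), P(T ≥ t))).
Fewer than two informative values on either side yields a missing p.

**Combination.** Local p-values are combined with the truncated product
method: W = Π {pᵢ : pᵢ ≤ τ}, default τ = 0.05 (the canonical truncation
point; τ = 1 recovers Fisher's method, and `tpm_pvalue_montecarlo`
reproduces the Fisher χ²₂ₖ tail under independence). Missing local
p-values are excluded from the product symmetrically in the observed and
every permuted statistic, so the null shares the observed missing pattern.
Eleven combined targets are formed: *to* each state (transitions ending
there), *from* each state, and *global* (all 24).

**Permutation null.** The permutation unit is the animal — all 24 of an
animal's probabilities move together — which is what makes the null
account for the correlation among local p-values. Two-sample comparisons
shuffle group labels; paired comparisons swap the two contexts
independently per animal, which is a sign flip of that animal's paired
differences (|d|, hence the ranks and exact nulls, are flip-invariant —
this is what makes 10,000-permutation runs cheap). All local tests and
combined statistics are recomputed identically per permutation, and
p = (1 + #{W_perm ≤ W_obs}) / (1 + n_perm), default n_perm = 10,000, so p
is never 0 and never below 1/(n_perm + 1).

**Multiplicity.** The five *to* and five *from* combined p-values are
Benjamini–Hochberg adjusted as one family of 10 per comparison (the
reading of "multiple combined tests corresponding to different syllables"
that covers both margins); `separate` and `none` family choices are
available. The single global p is reported unadjusted.

## Synthetic data

The symbolic generator draws each animal-context transition matrix rowwise
from a Dirichlet centered on an effect-modified group matrix
(concentration 50 by default: per-animal rows scatter with
sd ≈ √(p(1−p)/51), a moderate, realistic between-animal dispersion) and
emits bouts by Markov walk from silence to absorption at silence, which
makes the L + 1 transition identity hold by construction (walks are capped
at 200 syllables with a warning). Planted effects operate on the
probability scale with proportional renormalization of the remaining
mass: an additive to-silence shift (shorter bouts) and a multiplicative
suppression of transitions into `m` and out of `m` (reduced complex
sequencing). The default baseline matrix is invented on a realistic
topology (s-dominant bout starts; s/d/m self-loops; no u self-loop) — it
is a synthetic stand-in, never measured data. Cohort defaults (8 + 10
animals, 200 bouts per animal-context) mirror the scale of a typical
two-genotype study.

The audio generator renders note plans (frequency plateaus) as
constant-frequency sinusoids with 0.5 ms raised-cosine ramps, abutting
notes within a syllable, plus white Gaussian noise at a stated SNR, and
returns exact ground truth.

What passing the synthetic suites shows: the detector recovers boundaries
and labels perfectly for tonal, plateau-shaped syllables at SNR ≥ 30 dB;
the two-stage test is calibrated and powerful under Dirichlet-dispersed
Markov corpora. What it does not show: robustness to frequency sweeps,
harmonics, overlapping mechanical noise, reverberation, or real
between-animal heterogeneity beyond the Dirichlet model; higher-order
sequential dependence is out of scope by design (the analysis is
first-order Markov throughout).

## Numerical and validation choices

- Validation problem sizes: type-I error is measured over 500 effect-free
  cohort replicates (8 animals/group, 200 bouts each) at n_perm = 500 —
  the permutation-count reduction only coarsens the p-value grid to
  1/501, leaving the 5% rejection rate measurable; power against a +0.25
  to-silence shift uses 100 replicates at the same scale.
- Ties in permutation counting use `W_perm ≤ W_obs` with a 10⁻¹⁵
  tolerance; exact-null lookups use a 10⁻⁹ tolerance on mid-rank sums
  (mid-ranks are multiples of ½, so this is exact in float arithmetic).
- Degenerate inputs: all-tied local samples give p = 1; an all-missing
  combined target propagates NaN rather than raising; an empty truncated
  product is W = 1.
- Determinism: every stochastic routine takes a seed or Generator;
  identical (inputs, seed) give bit-identical corpora, permutations and
  results. Pipeline comparisons derive their seeds as config seed + index.

## Known limitations

- Single microphone, single vocalizer; no speaker attribution and no
  overlap resolution.
- Classification assumes jump magnitudes comfortably above the 10 kHz
  threshold; jumps near the threshold are assigned by a hard cut.
- The spectral amplitude reference (dB full scale) is a convention, not a
  calibrated sound-pressure level.
- The 35–125 kHz band and 250 ms bout threshold are defaults, not
  inferences; studies with different strains may need to re-examine both.
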