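# Methods

This note documents the models, parameter choices and numerical details
behind the package, and what its synthetic benchmarks do and do not show
about real EEG.

## Signal pipeline

Recordings are channels × samples matrices in microvolts at a nominal
1 kHz. Optional mastoid re-referencing subtracts the mean of the named
reference channels (average of both; the alternative "linked mastoid"
weightings differ only by a scale on the reference) and drops them,
matching the convention of a 60-analysis-channel montage referenced to
M1/M2.

**Band-pass filtering** uses a linear-phase Hamming-windowed FIR
(`scipy.signal.firwin`) applied forward and backward, so the effective
magnitude response is |H|² and the phase response is identically zero —
a requirement for unbiased instantaneous-phase estimates. Filter length
is four cycles of the band's lower edge (delta 0.5–4 Hz → 8 s at 1 kHz;
gamma 30–50 Hz → ~0.13 s), which yields ≥ 40 dB stopband rejection after
the two passes (a 60 Hz tone leaves < 1 % residual RMS through the gamma
filter). The two passes are implemented with FFT convolution and
odd-reflection edge padding; this is mathematically the same
forward–backward operation as `filtfilt` but O(N log N) in the number of
taps, which matters for the 8000-tap delta filter.

**Phase and envelope** come from the analytic signal
(`scipy.signal.hilbert`): phase = argument, envelope = modulus. Because
a zero-phase symmetric FIR contaminates (M−1)/2 samples at each end,
phase/amplitude statistics discard `min((M−1)/2, N/4)` samples per side;
the N/4 cap keeps a usable interior on short recordings (on a 150 s
study recording the trim is the full 4 s).

**Modulation index.** Phase is binned into N = 18 half-open bins of
2π/18 over [−π, π) (+π wraps into the last bin). Empty bins contribute
zero mean amplitude, and 0·log 0 ≡ 0 in the entropy; both situations are
guarded but unreachable with more than a few seconds of band-limited
data. Natural logarithms are used internally; MI is provably base-
invariant and the implementation exposes the base only so tests can
verify that. MI is computed on the full continuous segment per state;
block-wise computation is possible by slicing recordings upstream.

**Welch PSD.** `scipy.signal.welch` with an explicitly constructed
generalised Hamming taper `(1−a) − a·cos(2πn/(N−1))`, a = 0.46 by
default and configurable, 2 s segments, 50 % overlap, one-sided density
scaling. Integrating the density over frequency recovers the signal
variance (verified to < 1 % on white noise with ≥ 60 segments). The
band feature is `10·log10(scale · mean in-band density)`; `scale` is an
overall amplification constant (default 1). Absolute dB levels are only
meaningful relative to a fixed `scale`; all comparisons in the package
are differences, which `scale` cancels out of.

**Networks.** Pearson correlation over the full time course of the
band-filtered signals (zero-variance channels are rejected by name).
Binarisation keeps signed `r ≥ threshold` — published thresholds are
positive and negative-edge handling is never specified; an
absolute-value mode exists behind a flag. Degree is the adjacency row
sum; clustering is computed by networkx and cross-checked in the test
suite against an exhaustive triangle-counting oracle. C_i ≡ 0 for
k_i < 2 (the formula is 0/0 there). `select_threshold` scans a 0.01
grid from high to low and returns the largest threshold with no
isolated node and density inside a configured range (default
0.05–0.45), falling back with a warning to the no-isolated-node
criterion alone; edges are inclusive (`r ≥ thr`), so a matrix of
constant r = 0.9 selects 0.90, not 0.89.

**Statistics.** Wilcoxon signed-rank, two-sided, zero differences
dropped; exact null distribution for n ≤ 25 without tied |differences|,
otherwise the tie-corrected normal approximation. State contrasts pair
subjects (per channel, plus a whole-brain test on subject-wise channel
means). Group contrasts mirror the published procedure of applying a
paired test to two independent groups: the whole-brain contrast pairs
*per-channel group means across channels* (n = number of channels) —
this interpretation is an assumption and is labelled
`wilcoxon_signed_rank_over_channels` in every output row — while
per-channel subject-level contrasts use an unpaired rank-sum test.
Raw p-values at α = 0.05 are reported without multiplicity correction,
matching the per-node reporting convention; Benjamini–Hochberg is
available (`pacnet.stats.benjamini_hochberg`) but off by default.
Standard deviations use the n−1 denominator.

## Synthetic generator

Each channel is the amplitude-modulation construction

    x(t) = a_δ·sin θ(t) + a_γ·[(1 + χ·sin θ(t)) / (1 + χ)]·sin(2π f_γ t + ψ) + n(t)

with modulator phase θ(t) = 2π f_δ t + φ₀ + W(t), where W is a Wiener
process with diffusion `phase_drift` (default 2.0 rad²/s, ≈ 0.3 Hz
linewidth; 0 gives a strictly periodic carrier). The drift matters: with
a perfectly periodic modulator a circular amplitude shift only rotates
the preferred phase, to which MI is invariant, so surrogate controls
would be powerless; with drift the modulator decorrelates over ~1 s, as
real delta rhythm does, and shifted surrogates collapse to the
no-coupling floor. n(t) is 1/f^β noise (β = 1) made by spectral shaping
of seeded white noise.

Study-level structure: all channels of a recording share θ(t) (a common
slow modulator); each channel has a private gamma carrier phase and
private noise; channels are partitioned into `n_communities` contiguous
blocks (4 by default) that each share a latent pink-noise source of RMS
`mixing`, producing block-structured Pearson correlations.

Default parameters (microvolts): a_δ = 15, a_γ = 9, private noise
RMS = 2.5, community source RMS = 10, χ = 0.4, f_δ = 2 Hz, f_γ = 40 Hz.
These were fixed once by variance accounting so that (i) the delta and
gamma bands sit ≥ 10 dB above the 10–20 Hz background in a single
channel's Welch spectrum, and (ii) within-community correlations exceed
between-community ones by ≥ 0.2 (measured ≈ 0.4) — i.e. every pipeline
stage has a detectable ground truth to recover.

Condition effects are multipliers: the task state scales χ by
`task_chi_mult` = 1.8; stimulated-group ("tdcs") subjects get
χ × 0.85, a_δ × 0.894 (−0.97 dB) and a_γ × 1.16 (+1.32 dB) in every
state. The directions reproduce the reported phenomenology of anodal
DLPFC stimulation — less delta–gamma coupling, less delta power, more
gamma power than sham — and the magnitudes follow the published
whole-brain ratios; no attempt is made to match absolute printed values
(those depend on unavailable recordings and an unspecified dB
amplification constant).

### What the generator does *not* emulate

- artifacts (blinks, EMG), volume conduction, non-stationarity beyond
  the modulator drift, or event-locked trial structure;
- task-related *power* changes: only coupling depth carries the state
  effect. Note that the (1+χ) normalisation keeps the mean gamma
  *amplitude* χ-invariant but the mean gamma *power*
  (∝ (1+χ²/2)/(1+χ)²) still decreases slightly with χ (≈ −0.9 dB from
  rest to task at default settings), a small, sign-stable leak that the
  group contrasts are robust to;
- the delta-band correlation structure of real EEG: the shared
  modulator makes delta-band correlations high across *all* channels,
  so delta networks at the default 0.32 threshold are near-complete.
  Gamma networks carry the community structure.

Passing tests therefore demonstrate estimator correctness and
sensitivity under controlled conditions, not performance on artifactual
clinical data, which should be cleaned (ICA etc.) upstream.

## Problem sizes used in the automated checks

Coupling recovery and surrogate checks run 60 s single channels at
1 kHz, 20 seeds per χ. The null-calibration check runs 200 simulated
null studies and the direction check 50 replicates, both at a reduced
profile (200 Hz, 4–8 channels, 20–30 s, 12 subjects per group — the
study's own n). The reduced profiles were sized by power reasoning:
20–30 s at 200 Hz leaves ≥ 25 usable modulator cycles after edge
trimming, enough that the weakest injected effect (the 0.85 coupling
multiplier) is sign-stable when averaged over 12 subjects × 8 channels.
The full default study (3 groups × 12 subjects × 3 states, 60 channels,
150 s at 1 kHz) runs end-to-end in minutes but is not exercised by the
test suite.

## File formats

CSV recordings store samples as rows with a channel-label header; floats
are written as `%.17g` and parsed in round-trip mode, so write→read is
bit-exact and identical seeds give byte-identical files. EDF output is
16-bit with per-channel physical scaling over the observed range
(round-trip exact to one quantisation step, verified in tests); EDF
input is read through mne. Feature tables and comparison results are
long-format CSV; each run writes a manifest (config hash, version,
per-stage timings) for auditability.
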