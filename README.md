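# pacnet

Analysis of working-memory EEG through three complementary feature
families — delta–gamma **phase–amplitude coupling**, Welch **band power**,
and Pearson-correlation **brain networks** — together with the paired
nonparametric statistics used to compare task vs. rest states and
stimulated (tDCS) vs. sham groups, and a synthetic-EEG generator with
ground-truth coupling so every stage is verifiable without access to any
clinical recordings.

It is written for EEG researchers who want a tested, scriptable
implementation of these standard analyses: a plain Python API, small CSV/
EDF/JSON artifacts, and a thin CLI for batch runs.

## The measures

**Modulation index (MI).** The instantaneous delta phase (0.5–4 Hz,
zero-phase FIR + Hilbert transform) is divided into N = 18 bins of 20°;
the mean gamma envelope (30–50 Hz) per bin, normalised to a probability
vector *p*, is compared against the uniform distribution by a normalised
Kullback–Leibler divergence:

```
p(j) = ā_j / Σ_k ā_k        H(p) = −Σ_j p(j) log p(j)
KL   = log N − H(p)          MI   = KL / log N
```

MI = 0 means the gamma amplitude ignores the delta phase; MI = 1 means it
concentrates in a single phase bin. MI is invariant to the log base and
to rescaling of the amplitude series.

**Band power.** Welch's method (2 s Hamming segments, 50 % overlap,
one-sided density in µV²/Hz) reduced to `10·log10(mean in-band density)`
in dB per channel and band.

**Networks.** Pairwise Pearson correlation of the band-filtered signals,
binarised at a threshold (edge iff `r ≥ thr`); node degree
`k_i = Σ_j a_ij` and clustering coefficient `C_i = 2E_i/(k_i(k_i−1))`.
Thresholds are config values (defaults 0.32 delta / 0.56 gamma), with a
data-driven selector (no isolated nodes + density in range) for new data.

**Statistics.** Two-sided Wilcoxon signed-rank (exact for n ≤ 25 without
ties), per channel and on whole-brain means, reported as `mean ± sd` with
raw p-values at α = 0.05; between-group whole-brain contrasts pair
per-channel group means across channels, per-channel group contrasts use
an unpaired rank-sum test (labelled in the output).

## Worked example

`python examples/modulation_index.py` sweeps the generator's true
coupling depth χ and prints:

```
true chi ->  measured MI (18 phase bins, 60 s at 1 kHz)
   0.0   ->  0.00000
   0.2   ->  0.00293
   0.4   ->  0.01171
   0.6   ->  0.02673
   0.8   ->  0.04862

surrogate control at chi=0.8: intact MI 0.04862, median shifted MI 0.00096 (98% reduction)
```

The measured MI rank-orders the true modulation depth perfectly, the
zero-coupling floor is ~4 orders of magnitude below the χ = 0.8 value,
and circularly shifting the amplitude series (which preserves both
marginals but destroys their alignment) collapses MI by ~98 % — the
estimator responds to coupling, not to band power. The other examples
cover the generator (`simulate_coupled_eeg.py`), networks
(`brain_network.py`), paired statistics (`state_comparison.py`) and a
complete study run (`full_study.py`).

A full pipeline run is one call (or `pacnet run --config study.yml`):

```python
from pacnet import StudyConfig, run_study

config = StudyConfig.from_dict({
    "seed": 4,
    "synthetic": {"n_channels": 8, "fs": 200.0, "duration_s": 30.0,
                  "n_subjects_per_group": 6,
                  "groups": ["tdcs", "sham"],
                  "states": ["pre_rest", "task"]},
})
out = run_study(config, "study_out")   # features.csv, comparisons.csv, report.txt ...
```

Real recordings (EDF, or CSV with a channel-label header) are analysed
the same way via `input_dir` plus a `metadata.csv`; see
`pacnet.pipeline.load_recordings`.

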