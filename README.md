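# tdehmm

Transient, frequency-resolved network states in multichannel
electrophysiological recordings, via the **time-delay embedded hidden Markov
model (TDE-HMM)**.

Resting-state MEG/EEG source-space data show brief (tens to hundreds of
milliseconds) reoccurring episodes in which distributed brain regions
co-activate with distinct oscillatory power *and phase-coupling* signatures.
Sliding-window connectivity cannot resolve such events. The TDE-HMM finds
them directly: each time point `t` is augmented with lagged copies of every
channel over a window (e.g. 15 samples = 60 ms at 250 Hz), and a hidden
Markov model with **zero-mean Gaussian states** is fitted to a PCA reduction
of that embedded space. A state's covariance in the embedded space is the
multivariate autocovariance of the raw channels over the window — it encodes
spectral power and lagged cross-channel structure, hence frequency-resolved
phase coupling. The package is aimed at electrophysiologists analysing
source-reconstructed recordings, and at methods work needing a fully
inspectable desk-scale implementation with ground-truth simulations.

## What is implemented

- **Synthetic data** (`tdehmm.simulate`) — Markov-switching multichannel
  oscillator recordings with known state-specific carrier frequencies,
  cross-channel phase lags, noise, and per-subject random channel sign
  flips, so every downstream stage can be validated against ground truth.
- **Embedding** (`tdehmm.embedding`) — per-subject standardisation,
  time-delay embedding (channels × lags columns, no padding at edges), PCA
  by streaming covariance eigendecomposition (default `2 × n_channels`
  components).
- **Sign-flip alignment** (`tdehmm.signflip`) — resolves the per-subject
  dipole polarity ambiguity by maximising
  `Gain(f) = Σ_{j1,j2} Σ_α | Σ_s f_{s,j1} f_{s,j2} ρ_{s,j1,j2,α} / N |`
  over sign assignments `f ∈ {−1,+1}^{subjects×channels}`, where `ρ` is the
  lagged partial correlation between channels; greedy ascent with random
  restarts, plus an exhaustive maximiser for tiny instances.
- **HMM inference** (`tdehmm.hmm`) — conjugate variational Bayes with
  Dirichlet transition/initial posteriors and inverse-Wishart state
  covariances; scaled forward–backward on expected log-parameters; Viterbi
  decoding; monotone free energy; optional stochastic (minibatch-of-subjects)
  updates with Robbins–Monro step sizes.
- **Spectra** (`tdehmm.spectra`) — state-wise multitaper power, cross-spectra
  and coherence on the *original* channels (√γ sample weighting, DPSS
  tapers); non-negative matrix factorisation of state × pair coherence
  spectra into data-driven frequency modes; two-Gaussian-mixture connection
  thresholding and percentile power-map thresholding.
- **Dynamics** (`tdehmm.dynamics`) — dwell times, interval times, fractional
  occupancy, interval survival curves, point-process spectra of state
  onsets with block-bootstrap bands, across-state permutation tests, and
  the affine-invariant Riemannian distance between state autocovariances
  with a power-only / coherence-only decomposition.
- **Pipeline + CLI** (`tdehmm.pipeline`, `tdehmm` command) — one-config
  orchestration (simulate/load → sign-flip → embed → fit → spectra → stats)
  with TSV/YAML/HDF5 outputs.

## Worked example

Fit the bundled two-state benchmark (5 subjects × 60 s at 250 Hz, 8
channels; state 1 couples channel pairs at 4 Hz, state 2 at 10 Hz, both at
SNR 1):

```python
import numpy as np
from tdehmm import (two_state_config, simulate_dataset, embed_dataset,
                    LagWindow, FitOptions, fit)
from tdehmm.embedding import standardize
from tdehmm.spectra import statewise_multitaper
from tdehmm.dynamics import extract_visits, dwell_times, fractional_occupancy

config, specs = two_state_config(seed=7)
recordings, truth = simulate_dataset(config, specs)
emb = embed_dataset(recordings, LagWindow(15, config.fs), n_components=16)
posterior, stc = fit(emb, FitOptions(K=2, seed=0))

acc = np.mean([(p == t).mean() for p, t in zip(stc.viterbi_path, truth.true_paths)])
print(f"Viterbi accuracy vs ground truth: {max(acc, 1 - acc):.3f}")

ss = statewise_multitaper([standardize(r) for r in recordings], stc.gamma)
for k, pair in [(0, (0, 1)), (1, (4, 5))]:
    peak = ss.frequencies[np.argmax(ss.coherence[k, pair[0], pair[1]])]
    print(f"state {k + 1}: coherence of pair {pair} peaks at {peak:.1f} Hz")
```

prints

```
Viterbi accuracy vs ground truth: 0.970
state 1: coherence of pair (0, 1) peaks at 4.5 Hz
state 2: coherence of pair (4, 5) peaks at 9.5 Hz
```

The decoded hard state sequence matches the generating Markov path at 97%
of samples, and each recovered state's coherence spectrum peaks at its
generating carrier frequency to within the multitaper resolution
(half-bandwidth 2 Hz at the defaults). Dwell times and occupancies follow
from the Viterbi path (`extract_visits`, `dwell_times`,
`fractional_occupancy`): here mean dwells of roughly 230 ms per state with
near-equal occupancy, as dictated by the generating transition matrix.

The same analysis runs from the shell:

```sh
tdehmm run --out demo_out --seed 7
```

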