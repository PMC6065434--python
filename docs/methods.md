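# Methods

## Model

The observation model is a hidden Markov model over a time-delay embedded
representation of multichannel electrophysiological data. For channels
`x_1..x_C` sampled at `fs` Hz and a symmetric lag window
`α ∈ {−L..+L}` (default 15 samples, i.e. 60 ms at 250 Hz), the embedded
vector at time `t` is `y_t = (x_c(t+α))_{c,α} ∈ R^d`, `d = C(2L+1)`.
Each state `k` is a zero-mean Gaussian `N(0, Σ_k)` on this space: `Σ_k` is
the multivariate autocovariance of the channels over the window, which
captures per-channel spectral power (within-channel lag blocks) and lagged
cross-channel structure, i.e. frequency-resolved phase coupling
(cross-channel blocks). The state sequence is first-order Markov; exactly
one state is active per sample, with posterior uncertainty expressed by the
state time courses γ.

Because `d` grows quickly (42 channels × 15 lags = 630, with
`d(d−1)/2 = 198,135` free off-diagonal parameters per state), inference
runs on a PCA reduction of the embedded space. The default keeps
`2 × C` components; a component count that is not a multiple of `C` is
allowed but warned about, since after per-channel standardisation the
excess components explain variance from an essentially arbitrary channel
subset. PCA is computed by eigendecomposition of the pooled embedded
covariance, accumulated subject-by-subject (the concatenated matrix is
never held in memory); centering is global across subjects; components are
not whitened; component signs are fixed by making each component's
largest-magnitude loading positive. Embedded rows exist only where the full
window fits within one subject's recording — rows never span subject
boundaries — and state time courses are padded back to the original length
with uniform probabilities at the trimmed edges.

## Sign-flip alignment

Source reconstruction leaves each region's time course defined only up to
±1, inconsistently across subjects, which would partially cancel group-level
coupling estimates. Alignment maximises

    Gain(f) = Σ_{j1,j2} Σ_α | Σ_s f_{s,j1} f_{s,j2} ρ_{s,j1,j2,α} / N |

over `f ∈ {−1,+1}^{N×C}`, where `ρ_{s,j1,j2,α}` is the partial correlation
between `x_{j1}(t)` and `x_{j2}(t+α)` given all other channels at time `t`
(default lags −10..+10, giving 21 matrices per subject). Partialling makes
the sign relation between two channels direct; the measure is exactly
sign-equivariant (negating channel `j` negates row and column `j` of every
matrix), so candidate assignments are cheap to evaluate once ρ is computed.
Implementation details:

- Residualisation uses the lag-0 covariance, shrunk toward its diagonal
  with a Ledoit–Wolf-style closed-form intensity (ratio of summed
  estimation variances of the off-diagonal entries to their summed squared
  magnitudes) for stability on short recordings. One `C × C` inversion per
  subject; per-pair conditioning is completed by 2 × 2 Schur corrections.
- Diagonal (`j1 = j2`) terms of the gain are flip-invariant constants and
  are excluded; the argmax is unchanged.
- The search is greedy ascent over single (subject, channel) flips, visited
  in a fresh random order per sweep, accepting only strict improvements,
  stopping after a sweep with no accepted move; the best of `n_restarts`
  random initialisations (default 10) is returned. Exact maximisation is an
  NP-hard integer programme; an exhaustive maximiser is provided for tiny
  test instances only.
- The gain is invariant to negating all channels of one subject and to
  negating one channel across all subjects, so recovery is only defined up
  to this rank-one sign gauge; `flip_agreement` scores recovery after
  aligning to the closest gauge representative.

## Variational inference

Inference is conjugate variational Bayes with a structured posterior:
Dirichlet rows for the transition matrix, a Dirichlet initial distribution,
and an inverse-Wishart posterior per state covariance. Priors (weakly
informative, scale-aware): Dirichlet(1) for transitions and initial
probabilities; inverse-Wishart with scale `0.1 · Ĉ · (d+2)` and `d+2`
degrees of freedom, where `Ĉ` is the pooled data covariance. The
observation model has no mean parameter (zero mean is structural, not
estimated).

The E-step runs scaled forward–backward per subject on the expected
log-parameters (`exp E[log A]`, `exp E[log π]`, and
`E[log N(y; 0, Σ_k)]` under the Wishart precision posterior); the M-step
adds expected transition counts to the Dirichlet parameters and
γ-weighted scatter matrices to the inverse-Wishart scales. The free energy
(negative evidence lower bound) is the forward-recursion log-normaliser
minus the parameter KL terms; it is exactly non-increasing across full
E/M cycles and is the convergence criterion (relative change below 1e-6 by
default). States with occupancy below the embedded dimension keep the
prior covariance (with a warning); states with fewer than 10 occupied
samples are flagged as degenerate and not resurrected. Fitted states are
reported sorted by descending fractional occupancy for stable output.

Initialisation seeds each state's covariance from a random contiguous data
segment (deterministic given the seed). Stochastic mode updates the global
posteriors from minibatches of whole subjects: sufficient statistics are
rescaled by `n_subjects / batch_size` and blended into running statistics
with step sizes `ρ_i = (i + delay)^(−κ)` (defaults delay = 2, κ = 0.7); it
reaches a free energy within a fraction of a percent of the full-batch
optimum on the bundled benchmark given roughly twice the iteration count.

## State-wise spectra and frequency modes

Spectral descriptions are computed on the original (unembedded) channels so
the PCA step introduces no low-frequency bias. For each sliding window
(default 2 s, 50% overlap) and state `k`, the windowed data are multiplied
sample-wise by `sqrt(γ_k(t))` (or a Viterbi indicator for hard weighting),
tapered with DPSS sequences (default time-bandwidth 4, 7 tapers), and
cross-multiplied in the frequency domain; per-state accumulations are
normalised by total state weight. The square root makes each window's power
contribution linear in γ, so occupancy-weighted state spectra recombine to
the static whole-recording spectrum (exactly so for γ constant within a
window; within ~1% on the benchmark), while a 100 ms visit inside a 2 s
window still contributes only its own samples — this is what makes
coherence measurable for sub-cycle state visits. Coherence is
`|S_jk| / sqrt(S_jj S_kk)`. The frequency grid is the window's FFT grid
restricted to 1–45 Hz (0.5 Hz spacing, 89 bins, at the defaults); grid and
window are configurable. Note the estimator's resolution is the taper
half-bandwidth (time-bandwidth / window length = 2 Hz at the defaults), so
peak locations are only meaningful to that width; short visits additionally
broaden peaks by roughly the inverse dwell time.

Frequency modes are estimated by non-negative matrix factorisation of the
matrix `A` stacking the coherence spectrum of every (state, region pair)
row (K states × C(C−1)/2 pairs rows, F columns): `A ≈ WH`, elementwise
non-negative, classical multiplicative updates under the Frobenius
objective (non-increasing per update), best of 10 random restarts. Rows of
`H` are the frequency modes, reported sorted by spectral centroid; with
four modes on broadband data they correspond approximately to delta/theta,
alpha, beta and low-gamma, with the gamma mode typically least reliable at
realistic SNR. Power reuses the coherence-derived `H`: per-mode maps are
inner products of the respective spectra with the rows of `H`; wideband
summaries are plain averages over the grid.

For display, per-state/per-mode connection populations are thresholded by a
two-component 1-D Gaussian mixture (keep members of the higher-mean
component; keep none if BIC prefers a single component), and power maps by
the top percentile of |deviation from the across-state mean| (default 50%
wideband, 10% for frequency-specific maps).

## Temporal dynamics and state geometry

Dwell times, interval times and (hard) fractional occupancy are computed
from maximal runs of the Viterbi path; soft occupancy (column means of γ)
is available separately. Interval survival curves are empirical
`P(interval > x)`. State-onset rhythmicity is assessed by the multitaper
spectrum of the binary onset indicator series, with a stationary
block-bootstrap (10 s blocks, 99% percentile) confidence band — the
bootstrap destroys dependence beyond the block length, so a genuine
oscillatory mode appears as a peak escaping the band. Across-state
differences are tested by permutation: state labels are shuffled within
subject with a shared permutation set, the statistic is the across-subject
mean of (state value − mean of other states), and p-values use the add-one
estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, which is valid (never
zero, super-uniform under exchangeability).

Dissimilarity between states is the affine-invariant Riemannian distance
between their embedded-space autocovariances,
`d(C1, C2) = sqrt(Σ_i log² λ_i(C1⁻¹C2))` — symmetric, zero iff equal, and
invariant under congruence. A literal product form
`sqrt(Σ log λ_i(C1·C2))` is provided for comparison only; it is not a
metric (nonzero at `C1 = C2`, possibly imaginary) and is never the default.
The power/coherence decomposition manipulates the channel-block structure:
*power only* zeroes all cross-channel blocks; *coherence only* rescales
each channel's block to unit average diagonal, removing per-channel power
scale. Matrices lifted from PCA space (`B Σ_pca Bᵀ`) are rank-deficient and
receive a small diagonal load (1e-6 × mean diagonal) before distances.

## Synthetic data

The generator emulates the features the pipeline must detect: a first-order
Markov state sequence; within each state visit, specified channel pairs
carry a common sinusoid at the state's carrier frequency with a fixed phase
lag (phase continuous within a visit, reset to a uniform random phase at
each onset to avoid artificial cross-visit phase locking, and optionally a
distinct frequency per pair); independent Gaussian noise per channel; and
independent per-(subject, channel) sign flips. All randomness derives from
one master seed via per-subject child streams.

Two bundled configurations define the benchmark conditions:

- `two_state_config` — 5 subjects × 60 s at 250 Hz, 8 channels; state 1
  couples pairs (0,1) and (2,3) at 4 Hz, state 2 couples (4,5) and (6,7)
  at 10 Hz; SNR (sinusoid-to-noise variance per coupled channel) 1; stay
  probability 0.98 (mean dwell 200 ms — transient on the recording
  timescale while long enough to contain a cycle of the faster carrier).
- `chain_coupled_config` — the sign-flip benchmark: one state, channels
  coupled in a chain 0–1, 1–2, …, each pair at its own frequency. The
  chain makes every channel's sign identifiable, and per-pair frequencies
  keep non-adjacent channels incoherent; with a shared carrier all pairs
  would be mutually phase-locked at per-subject random phases, and the true
  signs would not even maximise the gain.

What the generator does **not** emulate: 1/f background spectra are off by
default (a first-order IIR-filtered noise option exists), and there is no
biophysical forward/inverse modelling, sensor-noise covariance, spatial
leakage, artefacts or non-stationarity beyond state switching. Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not robustness to the full complexity of real
recordings.

## Numerical choices and problem sizes

- Forward–backward uses per-step scaling; any finite log-likelihood input
  yields finite γ (emission rows are max-shifted before exponentiation).
- Viterbi ties break toward the lower state index.
- Exported tables use 1-based state IDs; everything internal is 0-based,
  time in seconds, frequency in Hz.
- Test problem sizes: exhaustive-path oracles at T ≤ 10, K ≤ 3; VB
  monotonicity over 50 random 240-sample datasets; the recovery benchmark
  at its native size (75,000 samples, 16 PCA components); sign-flip
  recovery over 20 seeded replicates of 5 subjects × 30 s; permutation
  calibration over 500 datasets of 6 states × 12 subjects with 199
  permutations. These sizes were chosen so the full suite characterises
  every stage while remaining desk-scale.

## Known limitations

- The HMM's state-exclusivity assumption makes absolute dwell/interval
  values interpretation-sensitive; relative comparisons between states are
  the intended use.
- Greedy sign-flip alignment finds local maxima; restarts mitigate but do
  not guarantee the global optimum, and signs of channels sharing no
  correlation path with the rest are unidentifiable in principle.
- The per-pair conditional in the lagged partial correlation conditions on
  lag-0 regressors; other conventions (per-lag symmetrised covariance) are
  defensible and would change ρ slightly, not its equivariance.
- NNMF factorisations are unique only under separability-type conditions;
  mode recovery is checked on constructions satisfying them.
- Multitaper peak locations are resolved only to the taper half-bandwidth,
  and sub-cycle visits bias peaks of slow carriers slightly upward.
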