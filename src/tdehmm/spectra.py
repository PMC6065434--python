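"""State-wise multitaper spectra, NNMF frequency modes and thresholding.

Spectral descriptions of the states are computed on the original
(unembedded) channels rather than from the state covariances, so the PCA
reduction used for inference introduces no low-frequency bias.  Each
sliding window is weighted sample-by-sample with sqrt(gamma_k) before
tapering, the field-standard state-wise multitaper: with the square root,
the per-window power contribution is linear in the state probability, so
occupancy-weighted state spectra sum back to the static spectrum, while a
short state visit inside a longer window still contributes only its own
samples to its state's estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss
from sklearn.mixture import GaussianMixture

from .simulate import SubjectRecording

__all__ = [
    "MultitaperConfig",
    "StateSpectra",
    "FrequencyModes",
    "statewise_multitaper",
    "nnmf_frequency_modes",
    "nnmf",
    "project_onto_modes",
    "wideband_average",
    "gmm_connection_threshold",
    "threshold_power_map",
]


@dataclass
class MultitaperConfig:
    window_seconds: float = 2.0
    time_bandwidth: float = 4.0
    n_tapers: int = 7
    fmin: float = 1.0
    fmax: float = 45.0
    overlap: float = 0.5
    weighting: str = "soft"  # "soft" (gamma) or "hard" (Viterbi indicator)

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*time_bandwidth - 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.weighting not in ("soft", "hard"):
            raise ValueError("weighting must be 'soft' or 'hard'")


@dataclass
class StateSpectra:
    """Per-state power, cross-spectra and coherence on a fixed frequency grid."""

    frequencies: np.ndarray     # F values in [fmin, fmax]
    psd: np.ndarray             # states x channels x F, >= 0
    csd: np.ndarray             # states x channels x channels x F, complex Hermitian
    coherence: np.ndarray       # states x channels x channels x F, in [0, 1]
    occupancy_weights: np.ndarray  # per-state total weight used

    @property
    def n_states(self) -> int:
        return self.psd.shape[0]

    @property
    def n_channels(self) -> int:
        return self.psd.shape[1]


@dataclass
class FrequencyModes:
    """NNMF factorisation A ~= W H of state x pair coherence spectra."""

    W: np.ndarray               # rows x n_modes
    H: np.ndarray               # n_modes x F, the spectral profiles ("frequency modes")
    frequencies: np.ndarray
    reconstruction_error: float  # relative Frobenius error
    mode_labels: list[str] = field(default_factory=list)
    mode_power: np.ndarray = None      # states x channels x n_modes
    mode_coherence: np.ndarray = None  # states x channels x channels x n_modes


def _state_weights(
    gamma: np.ndarray, viterbi_path: np.ndarray | None, K: int, weighting: str
) -> np.ndarray:
    if weighting == "soft":
        return gamma
    if viterbi_path is None:
        raise ValueError("hard weighting requires a Viterbi path")
    return np.eye(K)[viterbi_path]


def statewise_multitaper(
    recordings: list[SubjectRecording],
    gammas: list[np.ndarray],
    config: MultitaperConfig | None = None,
    viterbi_paths: list[np.ndarray] | None = None,
) -> StateSpectra:
    """Multitaper power/cross-spectra/coherence weighted by the state time courses.

    For each window w and state k, the windowed data are multiplied
    sample-wise by sqrt(w_k(t)) (w_k = gamma_k, or the Viterbi indicator
    for hard weighting), tapered with DPSS sequences and cross-multiplied
    in the frequency domain; per-state accumulations are normalised by the
    total state weight.  Coherence is |S_jk| / sqrt(S_jj S_kk).
    """
    if config is None:
        config = MultitaperConfig()
    fs = recordings[0].fs
    C = recordings[0].n_channels
    K = gammas[0].shape[1]
    nw = int(round(config.window_seconds * fs))
    step = max(1, int(round(nw * (1.0 - config.overlap))))
    tapers = dpss(nw, config.time_bandwidth, Kmax=config.n_tapers)  # n_tapers x nw
    freqs_full = np.fft.rfftfreq(nw, d=1.0 / fs)
    sel = (freqs_full >= config.fmin) & (freqs_full <= config.fmax)
    freqs = freqs_full[sel]
    F = int(sel.sum())

    csd = np.zeros((K, C, C, F), dtype=complex)
    weight_tot = np.zeros(K)
    for rec, gamma, vp in zip(
        recordings,
        gammas,
        viterbi_paths if viterbi_paths is not None else [None] * len(recordings),
    ):
        x = rec.data
        T = x.shape[0]
        if gamma.shape[0] != T:
            raise ValueError(
                f"gamma length {gamma.shape[0]} does not match recording length {T}"
            )
        w = _state_weights(gamma, vp, K, config.weighting)
        for start in range(0, T - nw + 1, step):
            seg = x[start : start + nw]
            wseg = np.sqrt(w[start : start + nw])  # nw x K
            for k in range(K):
                wk = wseg[:, k]
                mean_w = float((wk**2).mean())
                if mean_w == 0.0:
                    continue
                # taper the state-masked segment: n_tapers x nw x C
                tap = tapers[:, :, None] * (seg * wk[:, None])[None, :, :]
                X = np.fft.rfft(tap, axis=1)[:, sel, :]  # n_tapers x F x C
                csd[k] += np.einsum("mfa,mfb->abf", X, X.conj()) / config.n_tapers
                weight_tot[k] += mean_w
    missing = weight_tot == 0
    if missing.any():
        import warnings

        warnings.warn(
            f"state(s) {np.flatnonzero(missing).tolist()} have zero total weight; "
            "their spectra are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        csd /= np.where(weight_tot == 0, np.nan, weight_tot)[:, None, None, None]
        psd = np.real(np.einsum("kccf->kcf", csd.copy()))
        denom = np.sqrt(psd[:, :, None, :] * psd[:, None, :, :])
        coherence = np.abs(csd) / np.where(denom == 0, np.nan, denom)
    coherence = np.clip(coherence, 0.0, 1.0)
    return StateSpectra(
        frequencies=freqs,
        psd=psd,
        csd=csd,
        coherence=coherence,
        occupancy_weights=weight_tot,
    )


def nnmf(
    A: np.ndarray,
    n_modes: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Non-negative matrix factorisation A ~= WH by multiplicative updates.

    Frobenius objective; the classical Lee-Seung updates, under which the
    objective is non-increasing.  The best of ``n_restarts`` random
    initialisations (by reconstruction error) is returned.
    """
    A = np.asarray(A, float)
    if (A < 0).any():
        raise ValueError("NNMF input must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    norm_A = np.linalg.norm(A)
    best = None
    eps = 1e-12
    for _ in range(n_restarts):
        scale = np.sqrt(A.mean() / max(n_modes, 1))
        W = rng.random((A.shape[0], n_modes)) * scale + eps
        H = rng.random((n_modes, A.shape[1])) * scale + eps
        prev = np.inf
        for _it in range(max_iter):
            H *= (W.T @ A) / (W.T @ W @ H + eps)
            W *= (A @ H.T) / (W @ (H @ H.T) + eps)
            if _it % 10 == 0:
                err = np.linalg.norm(A - W @ H)
                if prev - err <= tol * max(norm_A, 1.0):
                    break
                prev = err
        err = float(np.linalg.norm(A - W @ H) / max(norm_A, eps))
        if best is None or err < best[2]:
            best = (W, H, err)
    return best


def nnmf_frequency_modes(
    spectra: StateSpectra,
    n_modes: int = 4,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
) -> FrequencyModes:
    """Data-driven frequency modes from state-wise coherence spectra.

    The input matrix A stacks the coherence spectrum of every (state,
    region pair) as rows -- (K states x C(C-1)/2 pairs) x F -- and is
    factorised as A = WH with non-negative factors.  Rows of H are the
    frequency modes (empirically: delta/theta, alpha, beta, low-gamma for
    n_modes=4).  Power reuses the coherence-derived H: per-mode power maps
    and coherence networks are projections of the respective spectra onto
    the rows of H.
    """
    K, C, F = spectra.psd.shape
    iu = np.triu_indices(C, k=1)
    rows = []
    for k in range(K):
        rows.append(spectra.coherence[k][iu[0], iu[1], :])  # pairs x F
    A = np.vstack(rows)
    A = np.nan_to_num(A, nan=0.0)
    W, H, err = nnmf(A, n_modes, seed=seed, n_restarts=n_restarts)
    # order modes by their spectral centroid (low to high frequency)
    centroid = (H * spectra.frequencies[None, :]).sum(axis=1) / np.maximum(
        H.sum(axis=1), 1e-12
    )
    order = np.argsort(centroid)
    W, H = W[:, order], H[order]
    labels = [f"mode{i + 1}" for i in range(n_modes)]
    mode_power = np.einsum("kcf,mf->kcm", np.nan_to_num(spectra.psd), H)
    mode_coh = np.einsum("kabf,mf->kabm", np.nan_to_num(spectra.coherence), H)
    return FrequencyModes(
        W=W,
        H=H,
        frequencies=spectra.frequencies,
        reconstruction_error=err,
        mode_labels=labels,
        mode_power=mode_power,
        mode_coherence=mode_coh,
    )


def project_onto_modes(spectrum_vector: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Inner product of an F-vector of power/coherence with each row of H."""
    v = np.asarray(spectrum_vector, float)
    if v.shape[-1] != H.shape[1]:
        raise ValueError("spectrum length does not match H columns")
    return v @ H.T


def wideband_average(spectrum_vector: np.ndarray, axis: int = -1) -> np.ndarray:
    """Simple average across all frequency bins (the wideband summary)."""
    return np.asarray(spectrum_vector, float).mean(axis=axis)


def gmm_connection_threshold(
    connection_values: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, dict]:
    """Keep only connections in the high-mean component of a 2-Gaussian mixture.

    A two-component 1-D Gaussian mixture is fitted by EM to the population
    of connection values; values whose posterior favours the higher-mean
    component are kept.  If BIC prefers a single Gaussian -- no connections
    stand out from the background -- nothing is kept.
    """
    v = np.asarray(connection_values, float).ravel()
    if v.size < 10:
        raise ValueError("need at least 10 connection values")
    X = v[:, None]
    report: dict = {}
    if np.ptp(v) == 0:
        return np.zeros(v.size, dtype=bool), {"n_components": 1, "reason": "constant"}
    try:
        gm1 = GaussianMixture(1, random_state=seed, n_init=1).fit(X)
        gm2 = GaussianMixture(2, random_state=seed, n_init=5).fit(X)
    except Exception as exc:  # EM failure: fall back to a single component
        import warnings

        warnings.warn(f"GMM fit failed ({exc}); keeping no connections", stacklevel=2)
        return np.zeros(v.size, dtype=bool), {"n_components": 1, "reason": "em_failure"}
    if gm1.bic(X) <= gm2.bic(X):
        report.update(n_components=1, bic1=gm1.bic(X), bic2=gm2.bic(X))
        return np.zeros(v.size, dtype=bool), report
    hi = int(np.argmax(gm2.means_.ravel()))
    post = gm2.predict_proba(X)
    keep = post[:, hi] > 0.5
    report.update(
        n_components=2,
        means=gm2.means_.ravel().tolist(),
        weights=gm2.weights_.ravel().tolist(),
        bic1=gm1.bic(X),
        bic2=gm2.bic(X),
    )
    return keep, report


def threshold_power_map(
    power_values: np.ndarray,
    percentile: float = 50.0,
    reference: np.ndarray | float | None = None,
) -> np.ndarray:
    """Keep the top ``percentile`` percent of |power - reference| deviations.

    ``reference`` defaults to the mean across the first axis (the
    across-state mean), so maps are displayed relative to the temporal
    average; activations and deactivations compete by magnitude.
    """
    x = np.asarray(power_values, float)
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must be in (0, 100]")
    if reference is None:
        reference = x.mean(axis=0, keepdims=True)
    dev = np.abs(x - reference)
    if percentile == 100.0:
        return np.ones_like(dev, dtype=bool)
    cut = np.quantile(dev, 1.0 - percentile / 100.0)
    return dev > cut
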