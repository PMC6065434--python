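"""Temporal dynamics of state visits and geometry of state covariances.

Covers dwell (life-)times, interval times and fractional occupancy of
state visits; survival curves of interval times; spectra of the state
onset point process; permutation testing of state-specific quantities
across subjects; and the affine-invariant Riemannian distance between
state autocovariance matrices, including a decomposition into power-only
and coherence-only contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.linalg import eigh
from scipy.signal.windows import dpss

__all__ = [
    "StateVisit",
    "extract_visits",
    "dwell_times",
    "interval_times",
    "fractional_occupancy",
    "interval_survival",
    "survival_at",
    "onset_spectrum",
    "permutation_test_across_states",
    "riemannian_distance",
    "state_distance_decomposition",
    "embedded_state_autocovariance",
]


@dataclass
class StateVisit:
    state_id: int
    onset_sample: int
    length_samples: int
    subject_id: str = "s0"


def extract_visits(
    viterbi_path: np.ndarray, fs: float | None = None, subject_id: str = "s0"
) -> list[StateVisit]:
    """Maximal runs of the hard state path; visits tile the path exactly."""
    p = np.asarray(viterbi_path)
    if p.size == 0:
        raise ValueError("empty path")
    change = np.flatnonzero(np.diff(p)) + 1
    onsets = np.concatenate(([0], change))
    ends = np.concatenate((change, [p.size]))
    return [
        StateVisit(int(p[a]), int(a), int(b - a), subject_id) for a, b in zip(onsets, ends)
    ]


def dwell_times(visits: list[StateVisit], fs: float) -> dict[int, np.ndarray]:
    """Per-state visit durations in milliseconds."""
    out: dict[int, list[float]] = {}
    for v in visits:
        out.setdefault(v.state_id, []).append(v.length_samples / fs * 1000.0)
    return {k: np.asarray(vals) for k, vals in out.items()}


def interval_times(visits: list[StateVisit], fs: float) -> dict[int, np.ndarray]:
    """Gaps between consecutive visits to the same state, in milliseconds."""
    last_end: dict[int, int] = {}
    out: dict[int, list[float]] = {}
    for v in visits:
        if v.state_id in last_end:
            gap = v.onset_sample - last_end[v.state_id]
            out.setdefault(v.state_id, []).append(gap / fs * 1000.0)
        last_end[v.state_id] = v.onset_sample + v.length_samples
    return {k: np.asarray(vals) for k, vals in out.items()}


def fractional_occupancy(
    gamma: np.ndarray | None = None,
    viterbi_path: np.ndarray | None = None,
    K: int | None = None,
) -> np.ndarray:
    """Proportion of time spent in each state.

    Soft version: column means of gamma.  Hard version: visit-length sums
    over the Viterbi path.  Either way the fractions sum to one.
    """
    if gamma is not None:
        g = np.asarray(gamma, float)
        return g.mean(axis=0)
    if viterbi_path is None:
        raise ValueError("provide gamma or a Viterbi path")
    p = np.asarray(viterbi_path)
    K = int(p.max()) + 1 if K is None else K
    return np.bincount(p, minlength=K) / p.size


def interval_survival(intervals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function of interval times.

    Returns (durations, proportion of intervals strictly longer), the
    right-continuous complement of the ECDF, decreasing from 1 toward 0.
    Evaluate at arbitrary x by step interpolation: S(x) = mean(intervals > x).
    """
    iv = np.sort(np.asarray(intervals, float))
    if iv.size == 0:
        raise ValueError("need at least one interval")
    x = np.concatenate(([0.0], iv))
    surv = 1.0 - np.searchsorted(iv, x, side="right") / iv.size
    return x, surv


def survival_at(intervals: np.ndarray, x: np.ndarray | float) -> np.ndarray:
    """S(x) = proportion of intervals strictly longer than x."""
    iv = np.sort(np.asarray(intervals, float))
    return 1.0 - np.searchsorted(iv, np.asarray(x, float), side="right") / iv.size


def onset_spectrum(
    viterbi_path: np.ndarray,
    fs: float,
    state: int | None = None,
    window_seconds: float = 10.0,
    time_bandwidth: float = 4.0,
    n_tapers: int = 7,
    fmax: float | None = None,
    n_boot: int = 200,
    block_seconds: float = 10.0,
    ci: float = 0.99,
    seed: int = 0,
) -> dict:
    """Multitaper spectrum of the state-onset point process, with bootstrap band.

    A state occurrence is the onset sample of a visit; the binary indicator
    series is mean-removed and multitapered over sliding windows.  The
    confidence band is a stationary block bootstrap (default 10 s blocks)
    percentile interval, quantifying what a rhythmicity peak must exceed.
    """
    p = np.asarray(viterbi_path)
    states = [state] if state is not None else sorted(np.unique(p).tolist())
    rng = np.random.default_rng(seed)
    nw = int(round(window_seconds * fs))
    tapers = dpss(nw, time_bandwidth, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(nw, 1.0 / fs)
    sel = freqs <= (fmax if fmax is not None else fs / 2)
    out: dict = {"frequencies": freqs[sel]}

    def _mt(series: np.ndarray) -> np.ndarray:
        T = series.size
        acc = np.zeros(sel.sum())
        n_win = 0
        step = nw // 2 if T > nw else nw
        for start in range(0, max(T - nw + 1, 1), step):
            seg = series[start : start + nw]
            if seg.size < nw:
                break
            seg = seg - seg.mean()
            X = np.fft.rfft(tapers * seg[None, :], axis=1)[:, sel]
            acc += (np.abs(X) ** 2).mean(axis=0)
            n_win += 1
        return acc / max(n_win, 1)

    block = max(1, int(round(block_seconds * fs)))
    for k in states:
        onsets = np.zeros(p.size)
        vis = extract_visits(p)
        idx = [v.onset_sample for v in vis if v.state_id == k]
        if len(idx) < 2:
            raise ValueError(f"state {k} has fewer than 2 onsets")
        onsets[idx] = 1.0
        spec = _mt(onsets)
        boots = np.empty((n_boot, spec.size))
        n_blocks = int(np.ceil(p.size / block))
        for b in range(n_boot):
            starts = rng.integers(0, p.size, size=n_blocks)
            pieces = [onsets[s : s + block] for s in starts]
            resampled = np.concatenate(pieces)[: p.size]
            if resampled.size < p.size:
                resampled = np.pad(resampled, (0, p.size - resampled.size))
            boots[b] = _mt(resampled)
        lo, hi = np.percentile(boots, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100], axis=0)
        out[k] = {"spectrum": spec, "band_low": lo, "band_high": hi}
    return out


def permutation_test_across_states(
    values: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> np.ndarray:
    """One p-value per state for "this state exceeds the mean of the others".

    ``values`` is states x subjects.  A shared set of permutations shuffles
    the state labels within each subject; the statistic is the across-subject
    mean of (state value - mean of the other states).  p-values use the
    permutation-inclusive add-one estimator, p = (1 + #{null >= obs}) / (1 + n_perm),
    so they are never zero and are valid under exchangeability.
    """
    v = np.asarray(values, float)
    K, S = v.shape
    if K < 2 or S < 2:
        raise ValueError("need at least 2 states and 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)

    def stat(m: np.ndarray) -> np.ndarray:
        tot = m.sum(axis=0)
        other_mean = (tot[None, :] - m) / (K - 1)
        return (m - other_mean).mean(axis=1)

    obs = stat(v)
    # shared permutation set: one K-permutation per (permutation, subject)
    orders = np.argsort(rng.random((n_perm, S, K)), axis=-1)  # n_perm x S x K
    permuted = np.take_along_axis(v.T[None, :, :], orders, axis=-1)  # n_perm x S x K
    tot = permuted.sum(axis=-1, keepdims=True)
    null = (permuted - (tot - permuted) / (K - 1)).mean(axis=1)  # n_perm x K
    exceed = (null >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_perm)


def riemannian_distance(
    C1: np.ndarray, C2: np.ndarray, literal_product_form: bool = False
) -> float:
    """Affine-invariant Riemannian distance between positive-definite matrices.

    d(C1, C2) = sqrt( sum_i log^2 lambda_i ) with lambda_i the generalized
    eigenvalues of (C1, C2).  Symmetric, zero iff C1 = C2, and invariant
    under congruence C -> M C M^T.

    ``literal_product_form`` instead evaluates sqrt(sum_i log lambda_i(C1*C2)),
    provided for comparison only: it is not a metric (it does not vanish at
    C1 = C2 and can be imaginary), so the affine-invariant form is the
    default.
    """
    C1 = np.asarray(C1, float)
    C2 = np.asarray(C2, float)
    for name, C in (("C1", C1), ("C2", C2)):
        w = np.linalg.eigvalsh((C + C.T) / 2.0)
        if w.min() <= 0:
            raise ValueError(
                f"{name} is not positive definite (smallest eigenvalue {w.min():.3e})"
            )
    if literal_product_form:
        lam = np.linalg.eigvals(C1 @ C2)
        total = np.log(np.abs(lam)).sum()
        return float(np.sqrt(total)) if total >= 0 else float("nan")
    lam = eigh(C1, C2, eigvals_only=True)
    return float(np.sqrt((np.log(lam) ** 2).sum()))


def embedded_state_autocovariance(posterior, pca_basis: np.ndarray, loading: float = 1e-6):
    """Lift state covariances from PCA space back to the embedded space.

    C_embedded = B Sigma_pca B^T is rank-deficient when components < embedded
    dimension, so a diagonal load (``loading`` x mean diagonal) restores
    positive definiteness for distance computations.
    """
    covs = posterior.expected_covariances()
    out = []
    for S in covs:
        C = pca_basis @ S @ pca_basis.T
        C = (C + C.T) / 2.0
        C += loading * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
        out.append(C)
    return np.asarray(out)


def _manipulate(C: np.ndarray, n_channels: int, n_lags: int, mode: str, loading: float):
    """Block manipulation of a channel-major embedded autocovariance."""
    d = n_channels * n_lags
    if C.shape != (d, d):
        raise ValueError(f"matrix shape {C.shape} does not match layout ({d}, {d})")
    if mode == "full":
        out = C.copy()
    elif mode == "power_only":
        # keep within-channel lag blocks, zero every cross-channel block
        out = np.zeros_like(C)
        for c in range(n_channels):
            sl = slice(c * n_lags, (c + 1) * n_lags)
            out[sl, sl] = C[sl, sl]
    elif mode == "coherence_only":
        # rescale so every channel block has unit average diagonal: removes
        # per-channel power while keeping relative (coupling) structure
        scales = np.empty(n_channels)
        for c in range(n_channels):
            sl = slice(c * n_lags, (c + 1) * n_lags)
            scales[c] = np.trace(C[sl, sl]) / n_lags
        D = np.repeat(1.0 / np.sqrt(scales), n_lags)
        out = C * np.outer(D, D)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = (out + out.T) / 2.0
    out += loading * np.trace(out) / d * np.eye(d)
    w = np.linalg.eigvalsh(out)
    if w.min() <= 0:
        raise ValueError(
            f"PD repair failed for mode {mode!r} (min eigenvalue {w.min():.3e})"
        )
    return out


def state_distance_decomposition(
    state_autocovariances: np.ndarray,
    n_channels: int,
    n_lags: int,
    mode: str = "full",
    loading: float = 1e-6,
) -> np.ndarray:
    """Pairwise Riemannian distances after isolating power or coherence.

    power_only zeroes all cross-channel blocks, so only within-channel
    autocovariance (spectral power) differences contribute; coherence_only
    normalises each within-channel block to unit average diagonal, removing
    per-channel power scale so only cross-channel (coupling) structure
    contributes; full leaves the matrices untouched.
    """
    mats = [
        _manipulate(np.asarray(C, float), n_channels, n_lags, mode, loading)
        for C in state_autocovariances
    ]
    K = len(mats)
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            D[i, j] = D[j, i] = riemannian_distance(mats[i], mats[j])
    return D
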