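"""Standardisation, time-delay embedding and PCA reduction.

The HMM operates on a time-delay embedded version of the data: each time
point is augmented with lagged copies of every channel over a symmetric
window, so that a zero-mean Gaussian state covariance in the embedded space
encodes the multivariate autocovariance (power and lagged cross-channel
structure, hence phase coupling) of the original signals.  Because the
embedded dimension grows as channels x lags, the embedded matrix is reduced
by PCA before inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .simulate import SubjectRecording

__all__ = [
    "LagWindow",
    "EmbeddedDataset",
    "standardize",
    "embed",
    "embedding_dimension",
    "offdiagonal_parameter_count",
    "pca_reduce",
    "embed_dataset",
]


@dataclass
class LagWindow:
    """Symmetric lag window, e.g. lags -7..+7 (= 15 samples = 60 ms at 250 Hz)."""

    n_lags: int = 15
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.n_lags < 1 or self.n_lags % 2 == 0:
            raise ValueError("n_lags must be a positive odd number (symmetric window)")

    @property
    def lags(self) -> np.ndarray:
        half = self.n_lags // 2
        return np.arange(-half, half + 1)

    @property
    def window_ms(self) -> float:
        return self.n_lags / self.fs * 1000.0

    @classmethod
    def from_window_ms(cls, window_ms: float, fs: float) -> "LagWindow":
        n = int(round(window_ms / 1000.0 * fs))
        if n % 2 == 0:
            n += 1
        return cls(n_lags=n, fs=fs)


@dataclass
class EmbeddedDataset:
    """Concatenated embedded + PCA-reduced data with subject bookkeeping."""

    reduced: np.ndarray                      # valid_time x n_components
    pca_basis: np.ndarray                    # (channels*n_lags) x n_components
    explained_variance_fraction: np.ndarray  # per component, non-increasing
    subject_boundaries: list[tuple[int, int]]  # half-open row ranges per subject
    lag_window: LagWindow
    n_channels: int
    mean: np.ndarray = field(default=None)   # embedded-space mean removed before projection

    @property
    def n_components(self) -> int:
        return self.reduced.shape[1]

    def subject_rows(self, s: int) -> np.ndarray:
        a, b = self.subject_boundaries[s]
        return self.reduced[a:b]


def standardize(recording: SubjectRecording) -> SubjectRecording:
    """Z-score each channel (per subject): mean 0, variance 1."""
    x = recording.data
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = [recording.channel_labels[i] for i in bad]
        raise ValueError(f"constant channel(s) cannot be standardized: {labels}")
    return SubjectRecording(
        (x - mu) / sd,
        recording.fs,
        subject_id=recording.subject_id,
        channel_labels=list(recording.channel_labels),
    )


def embed(recording: SubjectRecording | np.ndarray, lag_window: LagWindow) -> np.ndarray:
    """Time-delay embed a (time x channels) matrix.

    Row t of the result holds x_c(t + lag) for every channel c and lag in
    the window; edge samples whose window does not fit are dropped (no
    padding).  Columns are channel-major: column c * n_lags + i is channel c
    at lag lags[i], so each channel owns a contiguous block of n_lags
    columns (the layout the within/cross-channel block manipulations rely
    on).
    """
    x = recording.data if isinstance(recording, SubjectRecording) else np.asarray(recording, float)
    T, C = x.shape
    lags = lag_window.lags
    L = lags.size
    half = L // 2
    if T <= L:
        raise ValueError(f"recording length {T} too short for a {L}-sample window")
    n_valid = T - L + 1
    out = np.empty((n_valid, C * L))
    for i, lag in enumerate(lags):
        start = lag + half  # lag -half -> offset 0, lag +half -> offset L-1
        out[:, i::L] = x[start : start + n_valid, :]
    return out


def embedding_dimension(n_channels: int, n_lags: int) -> int:
    """Embedded-space dimension: channels x lags (42 x 15 = 630)."""
    if n_channels < 1 or n_lags < 1:
        raise ValueError("counts must be >= 1")
    return n_channels * n_lags


def offdiagonal_parameter_count(n_channels: int, n_lags: int) -> int:
    """Free off-diagonal parameters of the d x d state autocovariance, d(d-1)/2."""
    d = embedding_dimension(n_channels, n_lags)
    return d * (d - 1) // 2


def default_n_components(n_channels: int, factor: int = 2) -> int:
    """PCA component rule: a multiple of the channel count (default 2x).

    A non-multiple leaves the excess components explaining variance from an
    essentially arbitrary subset of channels, because after standardisation
    all channels carry equal variance.
    """
    return factor * n_channels


def pca_reduce(
    embedded_list: list[np.ndarray],
    n_components: int,
    lag_window: LagWindow,
    n_channels: int,
) -> EmbeddedDataset:
    """PCA on the concatenated embedded data via covariance eigendecomposition.

    The (d x d) covariance is accumulated subject-by-subject (streaming, so
    the concatenated matrix is never materialised beyond its rows), then
    eigendecomposed.  Centering is global across subjects.  Components are
    not whitened; the sign of each component is fixed by making its
    largest-magnitude loading positive.
    """
    d = embedded_list[0].shape[1]
    if n_components > d:
        raise ValueError(f"n_components {n_components} exceeds embedded dimension {d}")
    if n_components % n_channels != 0:
        warnings.warn(
            f"n_components={n_components} is not a multiple of n_channels="
            f"{n_channels}; the excess components will explain variance from "
            "an arbitrary subset of channels",
            stacklevel=2,
        )
    n_total = sum(e.shape[0] for e in embedded_list)
    mean = np.zeros(d)
    for e in embedded_list:
        mean += e.sum(axis=0)
    mean /= n_total
    cov = np.zeros((d, d))
    for e in embedded_list:
        ec = e - mean
        cov += ec.T @ ec
    cov /= n_total

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    rank = int((evals > evals[0] * 1e-12).sum()) if evals[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but data rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    basis = evecs[:, :n_components]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    basis = basis * flip[None, :]
    total_var = evals.sum()
    evf = evals[:n_components] / total_var if total_var > 0 else np.zeros(n_components)

    boundaries, reduced_parts, row = [], [], 0
    for e in embedded_list:
        reduced_parts.append((e - mean) @ basis)
        boundaries.append((row, row + e.shape[0]))
        row += e.shape[0]
    return EmbeddedDataset(
        reduced=np.vstack(reduced_parts),
        pca_basis=basis,
        explained_variance_fraction=evf,
        subject_boundaries=boundaries,
        lag_window=lag_window,
        n_channels=n_channels,
        mean=mean,
    )


def embed_dataset(
    recordings: list[SubjectRecording],
    lag_window: LagWindow | None = None,
    n_components: int | None = None,
) -> EmbeddedDataset:
    """Standardize, embed and PCA-reduce a multi-subject dataset.

    Embedded rows never span a subject boundary: each subject is embedded
    separately and the valid rows concatenated.
    """
    if lag_window is None:
        lag_window = LagWindow(15, recordings[0].fs)
    n_channels = recordings[0].n_channels
    if n_components is None:
        n_components = min(
            default_n_components(n_channels), n_channels * lag_window.n_lags
        )
    embedded = [embed(standardize(r), lag_window) for r in recordings]
    return pca_reduce(embedded, n_components, lag_window, n_channels)
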