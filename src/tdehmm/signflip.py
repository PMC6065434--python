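"""Resolution of the per-subject dipole sign ambiguity.

Source reconstruction determines each region's time course only up to an
arbitrary sign, inconsistently across subjects; group-level phase-coupling
estimates would partially cancel if left unaligned.  Alignment maximises
the across-subject consistency of lagged partial correlations:

    Gain(f) = sum_{j1,j2} sum_alpha | sum_s f_{s,j1} f_{s,j2} rho_{s,j1,j2,alpha} / N |

over sign assignments f in {-1,+1}^{subjects x channels}, where rho is the
lagged partial correlation between channels j1 (at lag 0) and j2 (at lag
alpha), conditioned on the remaining channels.  rho is sign-equivariant
(negating a channel negates its row and column), so Gain can be evaluated
cheaply for many candidate assignments; the search is a greedy ascent with
random restarts (exact maximisation is NP-hard).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .simulate import SubjectRecording

__all__ = [
    "LaggedPartialCorrSet",
    "lagged_partial_correlations",
    "gain",
    "greedy_signflip",
    "exhaustive_signflip",
    "apply_flips",
    "flip_agreement",
]


@dataclass
class LaggedPartialCorrSet:
    """rho[s, a, j1, j2] for lag offset lag_offsets[a]."""

    rho: np.ndarray  # subjects x lags x channels x channels
    lag_offsets: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.rho.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rho.shape[2]


def _shrunk_covariance(x: np.ndarray) -> np.ndarray:
    """Empirical covariance shrunk toward its diagonal.

    Ledoit-Wolf-style closed-form intensity: the ratio of the summed
    variances of the off-diagonal entries to their summed squared
    magnitudes, clipped to [0, 1].  Keeps the matrix well conditioned on
    short recordings while leaving the diagonal (hence sign equivariance)
    untouched.
    """
    n, _ = x.shape
    xc = x - x.mean(axis=0)
    S = xc.T @ xc / n
    # variance of each off-diagonal covariance estimate
    prods = np.einsum("ti,tj->tij", xc, xc)
    var_S = ((prods - S[None]) ** 2).sum(axis=0) / n**2
    off = ~np.eye(S.shape[0], dtype=bool)
    num = var_S[off].sum()
    den = (S[off] ** 2).sum()
    lam = 1.0 if den == 0 else min(1.0, max(0.0, num / den))
    out = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return out


def lagged_partial_correlations(
    recordings: list[SubjectRecording],
    lag_offsets: np.ndarray | None = None,
) -> LaggedPartialCorrSet:
    """Partial correlation of x_{j1}(t) with x_{j2}(t+alpha), given the rest.

    For each pair (j1, j2) both series are residualised on all other
    channels at time t (regression weights from the shrunken lag-0
    covariance), and the residuals correlated.  Partialling makes the
    measure direct -- no third channel mediates the sign relation between
    j1 and j2 -- and it is exactly sign-equivariant: negating channel j of
    one subject negates row j and column j of that subject's matrices at
    every lag.
    """
    if lag_offsets is None:
        lag_offsets = np.arange(-10, 11)
    lag_offsets = np.asarray(lag_offsets, dtype=int)
    if not np.array_equal(lag_offsets, -lag_offsets[::-1]):
        raise ValueError("lag_offsets must be symmetric about 0")
    C = recordings[0].n_channels
    S_count = len(recordings)
    L = lag_offsets.size
    rho = np.zeros((S_count, L, C, C))
    max_lag = int(np.abs(lag_offsets).max())
    for s, rec in enumerate(recordings):
        x = rec.data - rec.data.mean(axis=0)
        T = x.shape[0]
        if T <= 10 * max_lag:
            warnings.warn(
                f"subject {rec.subject_id}: recording length {T} is small "
                f"relative to max lag {max_lag}",
                stacklevel=2,
            )
        Sigma0 = _shrunk_covariance(x)
        n_used = T - 2 * max_lag
        base = x[max_lag : max_lag + n_used]  # x(t)
        for a, alpha in enumerate(lag_offsets):
            shifted = x[max_lag + alpha : max_lag + alpha + n_used]  # x(t+alpha)
            cross = base.T @ shifted / n_used  # cross[j1, j2] = cov(x_j1(t), x_j2(t+a))
            var_sh = (shifted**2).mean(axis=0)
            rho[s, a] = _pairwise_partial(Sigma0, cross, var_sh)
    return LaggedPartialCorrSet(rho=rho, lag_offsets=lag_offsets)


def _pairwise_partial(
    Sigma0: np.ndarray, cross: np.ndarray, var_shifted: np.ndarray
) -> np.ndarray:
    """Partial correlations for all ordered pairs, conditioning on the rest.

    Uses Schur complements against the full lag-0 precision so only one
    C x C inversion is needed; per pair only a 2 x 2 correction remains.
    """
    C = Sigma0.shape[0]
    theta = np.linalg.inv(Sigma0)
    out = np.zeros((C, C))
    for j1 in range(C):
        for j2 in range(C):
            if j1 == j2:
                continue
            idx = [j1, j2]
            O = [k for k in range(C) if k not in idx]
            # Sigma0[O,O]^-1 via the precision matrix: Theta_OO - Theta_Oj Theta_jj^-1 Theta_jO
            Tjj = theta[np.ix_(idx, idx)]
            TOj = theta[np.ix_(O, idx)]
            inv_OO_times = lambda v: theta[np.ix_(O, O)] @ v - TOj @ np.linalg.solve(Tjj, TOj.T @ v)
            s10 = Sigma0[j1, O]           # cov(x_j1(t), x_O(t))
            c0a = cross[O, j2]            # cov(x_O(t), x_j2(t+alpha))
            w1 = inv_OO_times(s10)
            pcov = cross[j1, j2] - s10 @ inv_OO_times(c0a)
            pvar1 = Sigma0[j1, j1] - s10 @ w1
            pvar2 = var_shifted[j2] - c0a @ inv_OO_times(c0a)
            denom = np.sqrt(max(pvar1, 1e-15) * max(pvar2, 1e-15))
            out[j1, j2] = np.clip(pcov / denom, -1.0, 1.0)
    return out


def gain(flips: np.ndarray, rho_set: LaggedPartialCorrSet) -> float:
    """Gain(f): summed magnitude of sign-aligned group-mean lagged partial correlations."""
    f = np.asarray(flips, float)
    if f.shape != (rho_set.n_subjects, rho_set.n_channels):
        raise ValueError("flip assignment shape does not match rho set")
    # M[a, j1, j2] = sum_s f_{s,j1} f_{s,j2} rho_{s,a,j1,j2} / N
    M = np.einsum("sj,sk,sajk->ajk", f, f, rho_set.rho) / rho_set.n_subjects
    off = ~np.eye(rho_set.n_channels, dtype=bool)
    return float(np.abs(M[:, off]).sum())


def greedy_signflip(
    rho_set: LaggedPartialCorrSet,
    n_restarts: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Greedy ascent on Gain with random sign initialisations.

    Single-(subject, channel) flip moves are accepted only if the gain
    strictly increases; cells are visited in a fresh random order each
    sweep; a restart terminates after a full sweep with no accepted move.
    Returns the best assignment over restarts and the per-restart gain
    traces (each non-decreasing).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, C = rho_set.n_subjects, rho_set.n_channels
    rho = rho_set.rho
    best_f, best_g, traces = None, -np.inf, []
    for r in range(n_restarts):
        f = rng.choice([-1.0, 1.0], size=(S, C))
        # M[a,j1,j2] maintained incrementally across accepted flips
        M = np.einsum("sj,sk,sajk->ajk", f, f, rho) / S
        off = ~np.eye(C, dtype=bool)
        g = float(np.abs(M[:, off]).sum())
        trace = [g]
        improved = True
        while improved:
            improved = False
            cells = rng.permutation(S * C)
            for cell in cells:
                s, j = divmod(cell, C)
                # flipping (s,j) changes row j and column j of M (off-diagonal part)
                delta_row = -2.0 * f[s, j] * f[s][None, :] * rho[s, :, j, :] / S
                delta_col = -2.0 * f[s, j] * f[s][None, :] * rho[s, :, :, j] / S
                new_row = M[:, j, :] + delta_row
                new_col = M[:, :, j] + delta_col
                mask = np.arange(C) != j
                dg = (
                    np.abs(new_row[:, mask]).sum()
                    - np.abs(M[:, j, mask]).sum()
                    + np.abs(new_col[:, mask]).sum()
                    - np.abs(M[:, mask, j]).sum()
                )
                if dg > 1e-12:
                    f[s, j] = -f[s, j]
                    M[:, j, :] = new_row
                    M[:, :, j] = new_col
                    M[:, j, j] = np.einsum("s,sa->a", f[:, j] * f[:, j], rho[:, :, j, j]) / S
                    g += dg
                    trace.append(g)
                    improved = True
        traces.append(np.asarray(trace))
        if g > best_g:
            best_g, best_f = g, f.copy()
    return best_f.astype(np.int8), traces


def exhaustive_signflip(rho_set: LaggedPartialCorrSet) -> tuple[np.ndarray, float]:
    """Brute-force maximiser over all 2^(S*C) assignments (tiny instances only)."""
    S, C = rho_set.n_subjects, rho_set.n_channels
    n = S * C
    if n > 20:
        raise ValueError("exhaustive search is only for tiny instances")
    best_f, best_g = None, -np.inf
    for bits in range(2**n):
        f = np.where(
            (bits >> np.arange(n)) & 1, -1.0, 1.0
        ).reshape(S, C)
        g = gain(f, rho_set)
        if g > best_g:
            best_g, best_f = g, f
    return best_f.astype(np.int8), float(best_g)


def apply_flips(
    recordings: list[SubjectRecording], flips: np.ndarray
) -> list[SubjectRecording]:
    """Multiply channel j of subject s by flips[s, j]; involution when repeated."""
    flips = np.asarray(flips)
    if flips.shape != (len(recordings), recordings[0].n_channels):
        raise ValueError(
            f"flips shape {flips.shape} does not match "
            f"({len(recordings)}, {recordings[0].n_channels})"
        )
    return [
        SubjectRecording(
            rec.data * flips[s][None, :],
            rec.fs,
            subject_id=rec.subject_id,
            channel_labels=list(rec.channel_labels),
        )
        for s, rec in enumerate(recordings)
    ]


def flip_agreement(recovered: np.ndarray, truth: np.ndarray, n_iter: int = 10) -> float:
    """Fraction of (subject, channel) signs recovered, modulo the gauge freedoms.

    Gain is invariant to negating all channels of one subject and to
    negating one channel across all subjects, so recovery is only defined
    up to a rank-one sign pattern a_s * b_j.  The relative signs
    r = recovered * truth are aligned to the closest such pattern by
    alternating majority votes, and the agreement fraction returned.
    """
    r = (np.asarray(recovered, float) * np.asarray(truth, float))
    a = np.ones(r.shape[0])
    b = np.ones(r.shape[1])
    for _ in range(n_iter):
        a = np.sign((r * b[None, :]).sum(axis=1))
        a[a == 0] = 1
        b = np.sign((r * a[:, None]).sum(axis=0))
        b[b == 0] = 1
    return float((r == a[:, None] * b[None, :]).mean())
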