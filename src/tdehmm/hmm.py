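"""Variational-Bayes inference for the zero-mean Gaussian HMM.

The observation model of each state is a zero-mean multivariate Gaussian
over the (PCA-reduced) time-delay embedded space, so a state is fully
described by a covariance matrix -- equivalently, by the multivariate
autocovariance of the original channels over the lag window, which encodes
both power and lagged cross-channel (phase-coupling) structure.

Inference is conjugate variational Bayes: Dirichlet posteriors over the
initial and transition distributions, inverse-Wishart posteriors over the
state covariances, and structured forward-backward over the state sequence
using exponentiated expected log-parameters.  The variational free energy
(negative evidence lower bound) is the convergence objective and is
non-increasing across full-batch iterations.  An optional stochastic mode
updates the global posteriors from minibatches of whole subjects with
Robbins-Monro step sizes, for datasets too long for full-batch sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.special import digamma, gammaln

from .embedding import EmbeddedDataset

__all__ = [
    "FitOptions",
    "HMMPosterior",
    "StateTimeCourses",
    "initialize",
    "e_step",
    "m_step",
    "free_energy",
    "fit",
    "viterbi",
    "forward_backward",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitOptions:
    K: int = 2
    max_iterations: int = 100
    tolerance: float = 1e-6        # relative free-energy change
    seed: int = 0
    stochastic: bool = False
    batch_size: int = 2            # subjects per minibatch
    step_delay: float = 2.0        # Robbins-Monro rho_i = (i + delay)^(-kappa)
    step_kappa: float = 0.7
    min_occupancy: float = 10.0    # below this a state is flagged as degenerate

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class HMMPosterior:
    """Posterior over HMM parameters (Dirichlet / inverse-Wishart family)."""

    K: int
    transition_posterior: np.ndarray   # K x K Dirichlet parameters (rows)
    initial_posterior: np.ndarray      # K Dirichlet parameters
    state_scales: np.ndarray           # K x d x d inverse-Wishart scale matrices
    state_dofs: np.ndarray             # K degrees of freedom, > d - 1
    prior_transition: np.ndarray = None
    prior_initial: np.ndarray = None
    prior_scale: np.ndarray = None     # d x d, shared across states
    prior_dof: float = None
    free_energy_trace: list = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.state_scales.shape[1]

    def expected_covariances(self) -> np.ndarray:
        """E[Sigma_k] = S_k / (nu_k - d - 1)."""
        d = self.dim
        denom = self.state_dofs - d - 1
        if (denom <= 0).any():
            raise ValueError("dof too small for a finite expected covariance")
        return self.state_scales / denom[:, None, None]

    def expected_transition_matrix(self) -> np.ndarray:
        a = self.transition_posterior
        return a / a.sum(axis=1, keepdims=True)

    def _emission_expectations(self) -> tuple[np.ndarray, np.ndarray]:
        """(E[Lambda_k], E[log det Lambda_k]) under the Wishart precision posterior."""
        K, d = self.K, self.dim
        e_prec = np.empty((K, d, d))
        e_logdet = np.empty(K)
        for k in range(K):
            S = self.state_scales[k]
            nu = self.state_dofs[k]
            sign, logdet_S = np.linalg.slogdet(S)
            if sign <= 0:
                raise ValueError(f"state {k} scale matrix is not positive definite")
            e_prec[k] = nu * np.linalg.inv(S)
            e_logdet[k] = (
                digamma((nu - np.arange(d)) / 2.0).sum() + d * np.log(2.0) - logdet_S
            )
        return e_prec, e_logdet


@dataclass
class StateTimeCourses:
    """Per-subject posterior state probabilities and hard paths.

    gamma rows sum to one; rows trimmed by the embedding window are padded
    back with the uniform distribution (and Viterbi with the nearest valid
    state) so every array aligns with the original recordings.
    """

    gamma: list[np.ndarray]            # per subject, time x K
    xi: list[np.ndarray]               # per subject, (time-1) x K x K joint pair probs
    viterbi_path: list[np.ndarray]     # per subject, 0-based ints
    log_evidence: float = 0.0


def _expected_log_dirichlet(alpha: np.ndarray) -> np.ndarray:
    alpha = np.atleast_2d(alpha)
    out = digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True))
    return out


def _dirichlet_kl(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    """KL(Dir(alpha_q) || Dir(alpha_p)) summed over rows."""
    aq = np.atleast_2d(alpha_q)
    ap = np.atleast_2d(alpha_p)
    a0q = aq.sum(axis=1)
    a0p = ap.sum(axis=1)
    kl = (
        gammaln(a0q)
        - gammaln(aq).sum(axis=1)
        - gammaln(a0p)
        + gammaln(ap).sum(axis=1)
        + ((aq - ap) * (digamma(aq) - digamma(a0q)[:, None])).sum(axis=1)
    )
    return float(kl.sum())


def _wishart_kl(Wq: np.ndarray, nuq: float, Wp: np.ndarray, nup: float) -> float:
    """KL between Wishart(Wq, nuq) and Wishart(Wp, nup) precisions."""
    d = Wq.shape[0]

    def log_B(W, nu):
        _, logdet = np.linalg.slogdet(W)
        return (
            -(nu / 2.0) * logdet
            - (nu * d / 2.0) * np.log(2.0)
            - (d * (d - 1) / 4.0) * np.log(np.pi)
            - gammaln((nu - np.arange(d)) / 2.0).sum()
        )

    _, logdet_q = np.linalg.slogdet(Wq)
    e_logdet = digamma((nuq - np.arange(d)) / 2.0).sum() + d * np.log(2.0) + logdet_q
    e_lambda_tr = nuq * np.trace(np.linalg.solve(Wp.T, Wq.T))  # tr(Wp^-1 E[Lambda]) / nuq * nuq
    kl = (
        log_B(Wq, nuq)
        - log_B(Wp, nup)
        + (nuq - nup) / 2.0 * e_logdet
        - nuq * d / 2.0
        + e_lambda_tr / 2.0
    )
    return float(kl)


def _as_subject_arrays(data) -> tuple[list[np.ndarray], object]:
    if isinstance(data, EmbeddedDataset):
        return [data.subject_rows(s) for s in range(len(data.subject_boundaries))], data
    arr = np.asarray(data, float)
    if arr.ndim != 2:
        raise ValueError("data must be 2-D or an EmbeddedDataset")
    return [arr], None


def initialize(data, options: FitOptions) -> HMMPosterior:
    """Seed K covariance posteriors from random contiguous data segments."""
    subjects, _ = _as_subject_arrays(data)
    rng = np.random.default_rng(options.seed)
    full = np.vstack(subjects)
    T, d = full.shape
    if not np.isfinite(full).all():
        raise ValueError("data contains non-finite values")
    K = options.K
    seg_len = max(d + 2, T // (2 * K))
    if T < seg_len:
        raise ValueError(f"not enough data ({T} rows) to draw {K} segments of {seg_len}")
    global_cov = full.T @ full / T
    prior_scale = 0.1 * global_cov * (d + 2)
    prior_dof = float(d + 2)
    scales = np.empty((K, d, d))
    dofs = np.full(K, prior_dof + seg_len)
    for k in range(K):
        start = int(rng.integers(0, T - seg_len + 1))
        seg = full[start : start + seg_len]
        scales[k] = prior_scale + seg.T @ seg
    return HMMPosterior(
        K=K,
        transition_posterior=np.ones((K, K)) + (T / K) * np.eye(K),
        initial_posterior=np.ones(K),
        state_scales=scales,
        state_dofs=dofs,
        prior_transition=np.ones((K, K)),
        prior_initial=np.ones(K),
        prior_scale=prior_scale,
        prior_dof=prior_dof,
    )


def _emission_loglik(y: np.ndarray, posterior: HMMPosterior) -> np.ndarray:
    """logB[t, k] = E_q[log N(y_t; 0, Sigma_k)] (T x K)."""
    e_prec, e_logdet = posterior._emission_expectations()
    d = y.shape[1]
    quad = np.einsum("ti,kij,tj->tk", y, e_prec, y)
    return -0.5 * d * LOG2PI + 0.5 * e_logdet[None, :] - 0.5 * quad


def forward_backward(
    logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward. Returns (gamma, xi, log-normaliser).

    Works for any finite log-emission matrix; scaling keeps the recursions
    in range so no input produces NaN.
    """
    T, K = logB.shape
    A = np.exp(log_A)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    c = np.empty(T)
    a0 = np.exp(log_pi) * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = alpha[:-1, :, None] * A[None] * (B[1:] * beta[1:])[:, None, :] / c[1:, None, None]
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    logZ = float(np.log(c).sum() + logB.max(axis=1).sum())
    return gamma, xi, logZ


def e_step(data, posterior: HMMPosterior) -> StateTimeCourses:
    """Posterior state probabilities under the current parameter posteriors."""
    subjects, _ = _as_subject_arrays(data)
    log_pi = _expected_log_dirichlet(posterior.initial_posterior)[0]
    log_A = _expected_log_dirichlet(posterior.transition_posterior)
    gammas, xis, paths = [], [], []
    total_logZ = 0.0
    for y in subjects:
        logB = _emission_loglik(y, posterior)
        gamma, xi, logZ = forward_backward(logB, log_pi, log_A)
        gammas.append(gamma)
        xis.append(xi)
        total_logZ += logZ
        paths.append(_viterbi_from_logs(logB, log_pi, log_A))
    return StateTimeCourses(gamma=gammas, xi=xis, viterbi_path=paths, log_evidence=total_logZ)


def _viterbi_from_logs(logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    delta = log_pi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        back[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi(data, posterior: HMMPosterior) -> list[np.ndarray]:
    """Most probable hard state sequence per subject under expected parameters."""
    subjects, _ = _as_subject_arrays(data)
    log_pi = _expected_log_dirichlet(posterior.initial_posterior)[0]
    log_A = _expected_log_dirichlet(posterior.transition_posterior)
    return [
        _viterbi_from_logs(_emission_loglik(y, posterior), log_pi, log_A)
        for y in subjects
    ]


def _suff_stats(subjects: list[np.ndarray], stc: StateTimeCourses, K: int):
    d = subjects[0].shape[1]
    scatter = np.zeros((K, d, d))
    occupancy = np.zeros(K)
    trans = np.zeros((K, K))
    init = np.zeros(K)
    for y, gamma, xi in zip(subjects, stc.gamma, stc.xi):
        occupancy += gamma.sum(axis=0)
        trans += xi.sum(axis=0)
        init += gamma[0]
        for k in range(K):
            yw = y * gamma[:, k : k + 1]
            scatter[k] += yw.T @ y
    return scatter, occupancy, trans, init


def m_step(data, stc: StateTimeCourses, posterior: HMMPosterior) -> HMMPosterior:
    """Conjugate updates: Dirichlet counts and gamma-weighted scatter matrices."""
    subjects, _ = _as_subject_arrays(data)
    K, d = posterior.K, posterior.dim
    scatter, occupancy, trans, init = _suff_stats(subjects, stc, K)
    scales = posterior.prior_scale[None] + scatter
    dofs = posterior.prior_dof + occupancy
    low = occupancy < d
    if low.any():
        warnings.warn(
            f"state(s) {np.flatnonzero(low).tolist()} have occupancy below the "
            f"embedded dimension ({d}); their covariance stays at the prior",
            stacklevel=2,
        )
        for k in np.flatnonzero(low):
            scales[k] = posterior.prior_scale
            dofs[k] = posterior.prior_dof
    return HMMPosterior(
        K=K,
        transition_posterior=posterior.prior_transition + trans,
        initial_posterior=posterior.prior_initial + init,
        state_scales=scales,
        state_dofs=dofs,
        prior_transition=posterior.prior_transition,
        prior_initial=posterior.prior_initial,
        prior_scale=posterior.prior_scale,
        prior_dof=posterior.prior_dof,
        free_energy_trace=posterior.free_energy_trace,
    )


def free_energy(data, posterior: HMMPosterior, stc: StateTimeCourses) -> float:
    """Negative evidence lower bound.

    F = -log Z~ + KL(q(A)||p(A)) + KL(q(pi)||p(pi)) + sum_k KL(q(Lambda_k)||p(Lambda_k)),
    where log Z~ is the forward-recursion normaliser computed with
    exponentiated expected log-parameters (the structured-VB identity that
    makes F exactly non-increasing over full e/m cycles).
    """
    kl = _dirichlet_kl(posterior.transition_posterior, posterior.prior_transition)
    kl += _dirichlet_kl(
        posterior.initial_posterior[None, :], posterior.prior_initial[None, :]
    )
    Wp = np.linalg.inv(posterior.prior_scale)
    for k in range(posterior.K):
        Wq = np.linalg.inv(posterior.state_scales[k])
        kl += _wishart_kl(Wq, posterior.state_dofs[k], Wp, posterior.prior_dof)
    return float(-stc.log_evidence + kl)


def _pad_state_time_courses(
    stc: StateTimeCourses, K: int, pad: int, full_lengths: list[int] | None
) -> StateTimeCourses:
    if pad == 0 or full_lengths is None:
        return stc
    gammas, paths = [], []
    for g, p in zip(stc.gamma, stc.viterbi_path):
        gp = np.full((g.shape[0] + 2 * pad, K), 1.0 / K)
        gp[pad : pad + g.shape[0]] = g
        gammas.append(gp)
        pp = np.concatenate((np.full(pad, p[0]), p, np.full(pad, p[-1])))
        paths.append(pp)
    return StateTimeCourses(
        gamma=gammas, xi=stc.xi, viterbi_path=paths, log_evidence=stc.log_evidence
    )


def _reorder_states(posterior: HMMPosterior, stc: StateTimeCourses) -> tuple:
    """Sort states by descending fractional occupancy for stable reporting."""
    occ = np.zeros(posterior.K)
    for g in stc.gamma:
        occ += g.sum(axis=0)
    order = np.argsort(-occ, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(posterior.K)
    post = HMMPosterior(
        K=posterior.K,
        transition_posterior=posterior.transition_posterior[np.ix_(order, order)],
        initial_posterior=posterior.initial_posterior[order],
        state_scales=posterior.state_scales[order],
        state_dofs=posterior.state_dofs[order],
        prior_transition=posterior.prior_transition,
        prior_initial=posterior.prior_initial,
        prior_scale=posterior.prior_scale,
        prior_dof=posterior.prior_dof,
        free_energy_trace=posterior.free_energy_trace,
    )
    stc2 = StateTimeCourses(
        gamma=[g[:, order] for g in stc.gamma],
        xi=[x[:, order][:, :, order] for x in stc.xi],
        viterbi_path=[inv[p] for p in stc.viterbi_path],
        log_evidence=stc.log_evidence,
    )
    return post, stc2


def fit(
    data, options: FitOptions, pad_to_original: bool = True
) -> tuple[HMMPosterior, StateTimeCourses]:
    """Alternate e/m steps until the relative free-energy change drops below
    tolerance (full-batch) or max_iterations is reached.

    In stochastic mode, minibatches of whole subjects update the global
    posteriors along a Robbins-Monro schedule rho_i = (i + delay)^(-kappa);
    sufficient statistics are rescaled by n_subjects / batch_size so each
    minibatch stands in for the full dataset.  States are reported sorted
    by descending fractional occupancy.
    """
    subjects, emb = _as_subject_arrays(data)
    K, d = options.K, subjects[0].shape[1]
    n_rows = sum(y.shape[0] for y in subjects)
    if n_rows < 10 * K * d:
        warnings.warn(
            f"only {n_rows} samples for K={K} states of dimension {d}; "
            "estimates may be unstable",
            stacklevel=2,
        )
    posterior = initialize(data, options)
    rng = np.random.default_rng(options.seed)
    if options.stochastic:
        posterior = _fit_stochastic(subjects, posterior, options, rng)
        stc = e_step(data, posterior)
        posterior.free_energy_trace.append(free_energy(data, posterior, stc))
    else:
        prev_f = np.inf
        stc = None
        for _ in range(options.max_iterations):
            stc = e_step(data, posterior)
            f = free_energy(data, posterior, stc)
            posterior.free_energy_trace.append(f)
            if not np.isfinite(f):
                raise RuntimeError(
                    f"free energy became non-finite at iteration "
                    f"{len(posterior.free_energy_trace)}"
                )
            if np.isfinite(prev_f) and abs(prev_f - f) <= options.tolerance * abs(prev_f):
                break
            prev_f = f
            posterior = m_step(data, stc, posterior)
    occ = np.zeros(K)
    for g in stc.gamma:
        occ += g.sum(axis=0)
    dead = occ < options.min_occupancy
    if dead.any():
        warnings.warn(
            f"state(s) {np.flatnonzero(dead).tolist()} are degenerate "
            f"(occupancy < {options.min_occupancy} samples)",
            stacklevel=2,
        )
    posterior, stc = _reorder_states(posterior, stc)
    if pad_to_original and emb is not None:
        pad = emb.lag_window.n_lags // 2
        lengths = [b - a + 2 * pad for a, b in emb.subject_boundaries]
        stc = _pad_state_time_courses(stc, K, pad, lengths)
    return posterior, stc


def _fit_stochastic(
    subjects: list[np.ndarray],
    posterior: HMMPosterior,
    options: FitOptions,
    rng: np.random.Generator,
) -> HMMPosterior:
    n_sub = len(subjects)
    batch = min(options.batch_size, n_sub)
    scale_factor = n_sub / batch
    # running natural-parameter statistics (posterior = prior + running stats)
    run_scatter = posterior.state_scales - posterior.prior_scale[None]
    run_occ = posterior.state_dofs - posterior.prior_dof
    run_trans = posterior.transition_posterior - posterior.prior_transition
    run_init = posterior.initial_posterior - posterior.prior_initial
    for i in range(options.max_iterations):
        rho = (i + 1 + options.step_delay) ** (-options.step_kappa)
        pick = rng.choice(n_sub, size=batch, replace=False)
        mini = [subjects[s] for s in pick]
        stc = StateTimeCourses(
            gamma=[], xi=[], viterbi_path=[], log_evidence=0.0
        )
        log_pi = _expected_log_dirichlet(posterior.initial_posterior)[0]
        log_A = _expected_log_dirichlet(posterior.transition_posterior)
        for y in mini:
            logB = _emission_loglik(y, posterior)
            gamma, xi, logZ = forward_backward(logB, log_pi, log_A)
            stc.gamma.append(gamma)
            stc.xi.append(xi)
            stc.log_evidence += logZ
        scatter, occ, trans, init = _suff_stats(mini, stc, options.K)
        run_scatter = (1 - rho) * run_scatter + rho * scale_factor * scatter
        run_occ = (1 - rho) * run_occ + rho * scale_factor * occ
        run_trans = (1 - rho) * run_trans + rho * scale_factor * trans
        run_init = (1 - rho) * run_init + rho * scale_factor * init
        posterior = HMMPosterior(
            K=options.K,
            transition_posterior=posterior.prior_transition + run_trans,
            initial_posterior=posterior.prior_initial + run_init,
            state_scales=posterior.prior_scale[None] + run_scatter,
            state_dofs=posterior.prior_dof + run_occ,
            prior_transition=posterior.prior_transition,
            prior_initial=posterior.prior_initial,
            prior_scale=posterior.prior_scale,
            prior_dof=posterior.prior_dof,
            free_energy_trace=posterior.free_energy_trace,
        )
    return posterior
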