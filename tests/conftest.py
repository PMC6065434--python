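import numpy as np
import pytest

from tdehmm.embedding import LagWindow, embed_dataset, standardize
from tdehmm.hmm import FitOptions, fit
from tdehmm.simulate import simulate_dataset, two_state_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_fit():
    """Fitted TDE-HMM on the bundled two-state coupled-oscillator benchmark.

    5 subjects x 60 s at 250 Hz, 8 channels, 4 Hz vs 10 Hz coupling; shared
    across tests because the fit is the most expensive single step.
    """
    config, specs = two_state_config(seed=7)
    recordings, truth = simulate_dataset(config, specs)
    emb = embed_dataset(recordings, LagWindow(15, config.fs), 16)
    posterior, stc = fit(emb, FitOptions(K=2, seed=0, max_iterations=40))
    standardized = [standardize(r) for r in recordings]
    return {
        "config": config,
        "specs": specs,
        "recordings": standardized,
        "truth": truth,
        "embedded": emb,
        "posterior": posterior,
        "stc": stc,
    }


def match_states(paths, true_paths, K):
    """Hungarian-matched hard-assignment accuracy between decoded and true paths."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((K, K))
    for p, tp in zip(paths, true_paths):
        for a in range(K):
            for b in range(K):
                conf[a, b] += np.sum((np.asarray(tp) == a) & (np.asarray(p) == b))
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / conf.sum(), dict(zip(r.tolist(), c.tolist()))
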