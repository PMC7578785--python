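import numpy as np
import pandas as pd
import pytest

from entrograd import behavior, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    return synthetic.TaskConfig(n_trials_per_run=16, n_runs=2, seed=3)


@pytest.fixture
def loss_averse_fit():
    """Typical loss-averse participant on the default currency scale."""
    return behavior.ParticipantFit(beta_gains=0.15, beta_losses=-0.30, intercept=0.1)


def simulate_trials(beta_gains, beta_losses, intercept, n, rng,
                    stake_low=0.25, stake_high=6.0, n_levels=16):
    """Bernoulli choices from a known model on a full stake crossing."""
    levels = np.linspace(stake_low, stake_high, n_levels)
    G, L = np.meshgrid(levels, levels, indexing="ij")
    cells = np.column_stack([G.ravel(), L.ravel()])
    idx = rng.permutation(len(cells))[:n] if n <= len(cells) else rng.integers(0, len(cells), n)
    g, l = cells[idx, 0], cells[idx, 1]
    from scipy.special import expit
    p = expit(beta_gains * g + beta_losses * l + intercept)
    return pd.DataFrame({"gain": g, "loss": l,
                         "accept": (rng.random(n) < p).astype(int)})
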