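import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import weberfit as w


@pytest.fixture
def exp2_design():
    """Four weight standards, 12 comparisons in 6 g steps, 12 repetitions."""
    return w.make_constant_stimuli_design([300, 350, 400, 450], 12, 6, 12)


@pytest.fixture
def exp3_design():
    """One 129 g standard at three brightness levels, 11 comparisons in 7 g steps."""
    return w.make_illusion_design()


def exact_points(pse, sigma, comparisons, n_per_level=10_000, lapse=0.0):
    """Binomial points whose proportions equal the model exactly (no sampling)."""
    comparisons = np.asarray(comparisons, dtype=float)
    p = lapse / 2 + (1 - lapse) * norm.cdf((comparisons - pse) / sigma)
    return pd.DataFrame(
        {
            "comparison": comparisons,
            "n_heavier": p * n_per_level,
            "n_total": float(n_per_level),
        }
    )


def grid_search_mle(points, pse_grid, sigma_grid, lapse=0.0):
    """Independent dense grid-search maximiser of the binomial likelihood.

    Pure numpy, no optimiser: evaluates the log-likelihood on the full
    (pse, sigma) grid and returns the best point and its NLL.
    """
    x = points["comparison"].to_numpy(dtype=float)
    k = points["n_heavier"].to_numpy(dtype=float)
    n = points["n_total"].to_numpy(dtype=float)
    P, S = np.meshgrid(pse_grid, sigma_grid, indexing="ij")
    prob = lapse / 2 + (1 - lapse) * norm.cdf((x[None, None, :] - P[..., None]) / S[..., None])
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    ll = np.sum(k * np.log(prob) + (n - k) * np.log1p(-prob), axis=-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(P[i, j]), float(S[i, j]), float(-ll[i, j])


def make_summary(participant, standards, means, sds, group="g"):
    return w.EstimationSummary(
        participant=participant,
        group=group,
        standards=np.asarray(standards, dtype=float),
        mean_estimate=np.asarray(means, dtype=float),
        sd_estimate=np.asarray(sds, dtype=float),
        n_trials=np.full(len(standards), 16),
    )
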