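"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own code paths: the probit posterior
is integrated on a dense 2-D grid rather than sampled, so it can arbitrate
the Gibbs sampler's output.
"""

import numpy as np
from scipy.special import ndtr


def probit_grid_oracle(scores, y, prior_sd, eval_scores,
                       lim: float = 15.0, n_grid: int = 301) -> np.ndarray:
    """Posterior predictive P(treated) by brute-force 2-D grid integration.

    The posterior over (intercept, slope) with Normal(0, prior_sd^2) priors
    is evaluated on an n_grid x n_grid lattice over [-lim, lim]^2 and the
    predictive probability at each evaluation score is the weighted mean of
    the probit link over the lattice.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    g = np.linspace(-lim, lim, n_grid)
    b0, b1 = np.meshgrid(g, g, indexing="ij")
    eta = b0[..., None] + b1[..., None] * scores
    loglik = np.where(y, np.log(ndtr(eta) + 1e-300),
                      np.log(ndtr(-eta) + 1e-300)).sum(axis=-1)
    logpost = loglik - (b0**2 + b1**2) / (2.0 * prior_sd**2)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return np.array([(w * ndtr(b0 + b1 * s)).sum() for s in np.atleast_1d(eval_scores)])
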