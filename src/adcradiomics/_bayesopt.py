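"""Minimal Gaussian-process Bayesian optimization (expected improvement).

Maximizes a black-box objective over a rectangular box.  Used for the
(log C, log gamma) hyperparameter search of the linear SVM; the budget is
deliberately small, so a plain GP with a Matern kernel and random-candidate
EI maximization is all that is needed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def maximize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    *,
    n_iter: int = 30,
    n_init: int = 8,
    n_candidates: int = 256,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[tuple[np.ndarray, float]]]:
    """Maximize ``objective`` over ``bounds`` with ``n_iter`` evaluations.

    Returns the best point and the full evaluation history.
    """
    rng = rng or np.random.default_rng()
    bounds = np.asarray(bounds, dtype=float)
    dim = len(bounds)
    n_init = min(n_init, n_iter)

    def draw(n: int) -> np.ndarray:
        return rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, dim))

    X = draw(n_init)
    y = np.array([objective(x) for x in X])

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(dim), nu=2.5)
    for _ in range(n_iter - n_init):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True, n_restarts_optimizer=0
        )
        gp.fit(X, y)
        cand = draw(n_candidates)
        mu, sigma = gp.predict(cand, return_std=True)
        x_next = cand[np.argmax(_expected_improvement(mu, sigma, y.max()))]
        X = np.vstack([X, x_next])
        y = np.append(y, objective(x_next))

    history = [(X[i], float(y[i])) for i in range(len(y))]
    return X[int(np.argmax(y))], history
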