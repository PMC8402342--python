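"""Seed-deterministic hyperparameter search: random and sequential model-based.

The selection pipeline needs two search strategies behind one contract:
a pure random search and a Bayesian (sequential model-based) search.  Both
maximize a black-box objective over a small box-constrained space and are
fully determined by an integer seed.  The Bayesian strategy fits a
Gaussian-process surrogate (scikit-learn ``GaussianProcessRegressor`` with a
Matern kernel) to past evaluations on the unit cube and proposes the point
maximizing expected improvement over a seeded candidate cloud; with very few
observations it falls back to random proposals, so a budget of 1-2 behaves
exactly like random search.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

#: A dimension is ("linear", lo, hi), ("log", lo, hi), ("int", lo, hi) or
#: ("choice", [values...]).
Space = Mapping[str, tuple]


def _to_unit(space: Space, params: Mapping[str, object]) -> np.ndarray:
    u = []
    for name, dim in space.items():
        kind = dim[0]
        v = params[name]
        if kind == "linear":
            u.append((float(v) - dim[1]) / (dim[2] - dim[1]))
        elif kind == "log":
            u.append(
                (math.log(float(v)) - math.log(dim[1]))
                / (math.log(dim[2]) - math.log(dim[1]))
            )
        elif kind == "int":
            u.append((float(v) - dim[1]) / max(dim[2] - dim[1], 1))
        elif kind == "choice":
            u.append(dim[1].index(v) / max(len(dim[1]) - 1, 1))
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return np.asarray(u)


def _from_unit(space: Space, u: np.ndarray) -> dict:
    params = {}
    for (name, dim), x in zip(space.items(), np.clip(u, 0.0, 1.0)):
        kind = dim[0]
        if kind == "linear":
            params[name] = dim[1] + x * (dim[2] - dim[1])
        elif kind == "log":
            params[name] = math.exp(
                math.log(dim[1]) + x * (math.log(dim[2]) - math.log(dim[1]))
            )
        elif kind == "int":
            params[name] = int(round(dim[1] + x * (dim[2] - dim[1])))
        elif kind == "choice":
            params[name] = dim[1][min(int(x * len(dim[1])), len(dim[1]) - 1)]
    return params


def sample_params(space: Space, rng: np.random.Generator) -> dict:
    """One random draw from the space (log dims sampled log-uniformly)."""
    return _from_unit(space, rng.random(len(space)))


def maximize(
    objective: Callable[[Mapping[str, object]], float],
    space: Space,
    budget: int,
    seed: int = 0,
    strategy: str = "random",
    n_init: int | None = None,
    n_candidates: int = 256,
) -> tuple[dict, float, list[tuple[dict, float]]]:
    """Maximize ``objective`` over ``space`` with ``budget`` evaluations.

    Parameters
    ----------
    strategy : "random" or "bayes".
    n_init : random evaluations before the surrogate kicks in (bayes only);
        default min(budget, max(3, len(space)+1)).

    Returns
    -------
    (best_params, best_value, history) with history a list of
    (params, value) in evaluation order.  Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if strategy not in ("random", "bayes"):
        raise ValueError(f"unknown search strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    if n_init is None:
        n_init = min(budget, max(3, len(space) + 1))

    history: list[tuple[dict, float]] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []

    for step in range(budget):
        if strategy == "random" or step < n_init:
            params = sample_params(space, rng)
        else:
            params = _propose_ei(space, X_obs, y_obs, rng, n_candidates)
        value = float(objective(params))
        history.append((params, value))
        X_obs.append(_to_unit(space, params))
        y_obs.append(value)

    best_idx = int(np.argmax(y_obs))
    return history[best_idx][0], y_obs[best_idx], history


def _propose_ei(
    space: Space,
    X_obs: Sequence[np.ndarray],
    y_obs: Sequence[float],
    rng: np.random.Generator,
    n_candidates: int,
) -> dict:
    """Expected-improvement proposal from a GP surrogate on the unit cube."""
    X = np.vstack(X_obs)
    y = np.asarray(y_obs)
    y_mean, y_sd = y.mean(), y.std()
    y_std = (y - y_mean) / (y_sd if y_sd > 0 else 1.0)
    gp = GaussianProcessRegressor(
        kernel=Matern(length_scale=0.3, nu=2.5),
        alpha=1e-6,
        normalize_y=False,
        random_state=0,
        optimizer=None,  # fixed kernel: cheap and fully deterministic
    )
    gp.fit(X, y_std)
    cands = rng.random((n_candidates, len(space)))
    mu, sigma = gp.predict(cands, return_std=True)
    best = y_std.max()
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
    return _from_unit(space, cands[int(np.argmax(ei))])
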