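"""Sequential model-based (Bayesian) minimization over small mixed spaces.

A Gaussian-process surrogate with a Matern kernel is fitted to the evaluated
points (categoricals one-hot encoded, integer dimensions optionally
log-scaled) and the next point is chosen by maximizing expected improvement
over a random candidate pool.  A pure random-search fallback is available
behind the same interface.  Deterministic given the seed.

This is sized for hyperparameter spaces of a handful of dimensions and
budgets of tens of evaluations, which is all the KNN tuning here needs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel

__all__ = ["Integer", "Categorical", "bayes_minimize", "random_minimize"]


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int
    log: bool = False

    def sample(self, rng: np.random.Generator) -> int:
        if self.log:
            return int(round(np.exp(rng.uniform(np.log(self.low),
                                                np.log(self.high)))))
        return int(rng.integers(self.low, self.high + 1))

    def encode(self, v) -> list[float]:
        return [math.log(v) if self.log else float(v)]


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[rng.integers(len(self.choices))]

    def encode(self, v) -> list[float]:
        return [1.0 if c == v else 0.0 for c in self.choices]


def _encode(space, params: dict) -> np.ndarray:
    out: list[float] = []
    for dim in space:
        out.extend(dim.encode(params[dim.name]))
    return np.array(out)


def _sample(space, rng) -> dict:
    return {dim.name: dim.sample(rng) for dim in space}


def random_minimize(objective: Callable[[dict], float], space: Sequence,
                    n_calls: int = 30, seed: int = 0,
                    n_initial: int | None = None) -> tuple[dict, float, list]:
    """Uniform random search; same return signature as :func:`bayes_minimize`."""
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(n_calls):
        p = _sample(space, rng)
        trace.append((p, float(objective(p))))
    best = min(trace, key=lambda t: t[1])
    return best[0], best[1], trace


def bayes_minimize(objective: Callable[[dict], float], space: Sequence,
                   n_calls: int = 30, seed: int = 0,
                   n_initial: int = 8,
                   n_candidates: int = 400) -> tuple[dict, float, list]:
    """Minimize ``objective`` over ``space`` by GP expected improvement.

    Returns (best_params, best_value, trace) where trace is the list of
    (params, value) pairs in evaluation order — best-so-far is monotone
    non-increasing along it by construction of the min.
    """
    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []
    seen: set[tuple] = set()

    def key(p: dict) -> tuple:
        return tuple(p[d.name] for d in space)

    def evaluate(p: dict) -> None:
        trace.append((p, float(objective(p))))
        seen.add(key(p))

    for _ in range(min(n_initial, n_calls)):
        evaluate(_sample(space, rng))

    while len(trace) < n_calls:
        X = np.vstack([_encode(space, p) for p, _ in trace])
        yv = np.array([v for _, v in trace])
        y_mean, y_std = yv.mean(), max(yv.std(), 1e-12)
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.ones(X.shape[1]),
                          length_scale_bounds=(1e-2, 1e3))
            + WhiteKernel(noise_level=1e-4,
                          noise_level_bounds=(1e-8, 1e1)),
            normalize_y=False, random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, (yv - y_mean) / y_std)
        cands = [_sample(space, rng) for _ in range(n_candidates)]
        cands = [c for c in cands if key(c) not in seen] or cands
        Xc = np.vstack([_encode(space, c) for c in cands])
        mu, sigma = gp.predict(Xc, return_std=True)
        best_y = (yv.min() - y_mean) / y_std
        sigma = np.maximum(sigma, 1e-12)
        z = (best_y - mu) / sigma
        ei = sigma * (z * norm.cdf(z) + norm.pdf(z))
        evaluate(cands[int(np.argmax(ei))])

    best = min(trace, key=lambda t: t[1])
    return best[0], best[1], trace
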