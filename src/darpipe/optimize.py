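"""Sequential model-based (Bayesian) hyperparameter search.

A Gaussian-process surrogate with a Matern-5/2 kernel models the objective
over the unit hypercube (log-scaled dimensions where declared); after a
random warm-up phase, each new trial maximises expected improvement over a
random candidate pool.  Fully deterministic under the supplied seed, and
degrades gracefully to pure random search if the surrogate fit fails.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclasses.dataclass(frozen=True)
class Dimension:
    """One hyperparameter: a float/int range, optionally log-scaled."""

    name: str
    kind: str  # "float" | "int"
    low: float
    high: float
    log: bool = False

    def to_unit(self, value: float) -> float:
        lo, hi = (math.log(self.low), math.log(self.high)) if self.log else (self.low, self.high)
        v = math.log(value) if self.log else value
        return (v - lo) / (hi - lo)

    def from_unit(self, u: float):
        lo, hi = (math.log(self.low), math.log(self.high)) if self.log else (self.low, self.high)
        v = lo + float(np.clip(u, 0.0, 1.0)) * (hi - lo)
        if self.log:
            v = math.exp(v)
        if self.kind == "int":
            return int(round(v))
        return float(v)


class BayesianSearch:
    """Ask/tell optimiser maximising a noisy objective over a search space."""

    def __init__(self, space: Mapping[str, Dimension], n_evals: int, seed: int = 0,
                 n_init: int | None = None, pool_size: int = 256):
        if n_evals < 1:
            raise ValueError("need at least one evaluation")
        self.space = dict(space)
        self.dims = list(self.space.values())
        self.n_evals = n_evals
        self.n_init = n_init if n_init is not None else max(4, n_evals // 5)
        self.pool_size = pool_size
        self.rng = np.random.default_rng(seed)
        self.X: list[np.ndarray] = []
        self.y: list[float] = []

    def _decode(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(u[i]) for i, d in enumerate(self.dims)}

    def ask(self) -> dict:
        k = len(self.dims)
        if len(self.X) < self.n_init or len(self.X) < 2:
            u = self.rng.uniform(size=k)
            self._pending = u
            return self._decode(u)
        X = np.vstack(self.X)
        y = np.asarray(self.y)
        kernel = Matern(length_scale=np.full(k, 0.3), nu=2.5,
                        length_scale_bounds=(1e-2, 10.0))
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-4,
                                      normalize_y=True,
                                      random_state=int(self.rng.integers(2 ** 31)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, y)
            pool = self.rng.uniform(size=(self.pool_size, k))
            mu, sd = gp.predict(pool, return_std=True)
            best = y.max()
            sd = np.maximum(sd, 1e-9)
            z = (mu - best) / sd
            ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
            u = pool[int(np.argmax(ei))]
        except Exception:  # surrogate failure -> random fallback
            u = self.rng.uniform(size=k)
        self._pending = u
        return self._decode(u)

    def tell(self, objective: float) -> None:
        self.X.append(self._pending)
        self.y.append(float(objective))

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.y))
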