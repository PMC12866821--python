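"""Gaussian-process Bayesian minimization over mixed search spaces.

Small self-contained replacement for a skopt-style optimizer: real
(uniform / log-uniform), integer and categorical dimensions; expected-
improvement acquisition maximized over seeded random candidates; hard
iteration budget and early stopping after a fixed number of consecutive
non-improving evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .errors import ConfigurationError


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    prior: str = "uniform"  # "uniform" | "log-uniform"
    name: str = ""

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ConfigurationError(f"Real dimension {self.name}: high < low")
        if self.prior == "log-uniform" and self.low <= 0:
            raise ConfigurationError(f"Real dimension {self.name}: log prior needs low > 0")

    def to_unit(self, x: float) -> float:
        if self.low == self.high:
            return 0.0
        if self.prior == "log-uniform":
            return (np.log(x) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        if self.prior == "log-uniform":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        return float(self.low + u * (self.high - self.low))

    def is_point(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class Integer:
    low: int
    high: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ConfigurationError(f"Integer dimension {self.name}: high < low")

    def to_unit(self, x: int) -> float:
        if self.low == self.high:
            return 0.0
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> int:
        return int(round(self.low + u * (self.high - self.low)))

    def is_point(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class Categorical:
    choices: tuple
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.choices) == 0:
            raise ConfigurationError(f"Categorical dimension {self.name}: empty choices")

    def to_unit(self, x) -> float:
        if len(self.choices) == 1:
            return 0.0
        return self.choices.index(x) / (len(self.choices) - 1)

    def from_unit(self, u: float) -> Any:
        idx = int(round(u * (len(self.choices) - 1)))
        return self.choices[idx]

    def is_point(self) -> bool:
        return len(self.choices) == 1


Dimension = Real | Integer | Categorical


@dataclass
class OptimizeResult:
    best_point: list
    best_value: float
    trace: list[tuple[list, float]] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def n_evaluations(self) -> int:
        return len(self.trace)


def gp_minimize(
    objective: Callable[[list], float],
    space: Sequence[Dimension],
    max_iterations: int = 100,
    patience: int = 20,
    n_initial: int = 10,
    n_candidates: int = 256,
    seed: int = 0,
) -> OptimizeResult:
    """Minimize ``objective`` over ``space`` with a GP surrogate.

    Stops after ``max_iterations`` evaluations, or as soon as ``patience``
    consecutive evaluations fail to improve on the incumbent. A degenerate
    single-point space is evaluated exactly once.
    """
    if not space:
        raise ConfigurationError("search space must be non-empty")
    if patience >= max_iterations:
        raise ConfigurationError("patience must be < max_iterations")
    rng = np.random.default_rng(seed)
    dims = list(space)

    def decode(u: np.ndarray) -> list:
        return [d.from_unit(float(v)) for d, v in zip(dims, u)]

    if all(d.is_point() for d in dims):
        point = decode(np.zeros(len(dims)))
        value = float(objective(point))
        return OptimizeResult(best_point=point, best_value=value, trace=[(point, value)])

    U: list[np.ndarray] = []
    trace: list[tuple[list, float]] = []
    best_value = np.inf
    best_point: list = []
    stall = 0
    stopped_early = False

    for it in range(max_iterations):
        if it < n_initial or len(trace) < 2:
            u = rng.random(len(dims))
        else:
            y = np.array([v for _, v in trace])
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6,
                random_state=int(rng.integers(2**31)),
            )
            gp.fit(np.array(U), y)
            cand = rng.random((n_candidates, len(dims)))
            mean, sd = gp.predict(cand, return_std=True)
            sd = np.maximum(sd, 1e-12)
            imp = best_value - mean
            zsc = imp / sd
            ei = imp * norm.cdf(zsc) + sd * norm.pdf(zsc)
            u = cand[int(np.argmax(ei))]
        point = decode(u)
        value = float(objective(point))
        U.append(np.array([d.to_unit(p) for d, p in zip(dims, point)]))
        trace.append((point, value))
        if value < best_value:
            best_value = value
            best_point = point
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                stopped_early = True
                break

    return OptimizeResult(
        best_point=best_point, best_value=best_value, trace=trace,
        stopped_early=stopped_early,
    )
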