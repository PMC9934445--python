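"""Offline linear discriminant analysis references.

For two Gaussian classes with shared covariance,

    p(x | y=0) = N(mu0, Sigma),   p(x | y=1) = N(mu1, Sigma),

the optimal linear rule assigns class 0 when ``w_opt . x > b_opt`` with

    w_opt = Sigma^{-1} (mu0 - mu1),
    b_opt = 1/2 w_opt . (mu0 + mu1) + log(pi1 / pi0).

``w_opt`` also minimises the convex objective

    L(w) = -w . (mu0 - mu1) + 1/2 w^T Sigma w,

whose gradient descent ``w <- w + eta (mu0 - mu1 - Sigma w)`` and gradient
flow ``w'(t) = mu0 - mu1 - Sigma w(t)`` both converge to it.  These closed
forms serve as oracles for the online algorithm in :mod:`mblda.online`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.special import ndtr

from .errors import ConfigError, DimensionError, IllConditionedError

__all__ = [
    "ClassStatistics",
    "OfflineSolution",
    "lda_objective",
    "optimal_solution",
    "gradient_step",
    "gradient_flow",
]

#: condition number above which covariance solves are refused
CONDITION_LIMIT = 1e12


@dataclass(frozen=True, eq=False)
class ClassStatistics:
    """Population statistics of a two-class equal-covariance Gaussian model.

    ``pi1`` is the class-1 (DAN-active) frequency; ``pi0 = 1 - pi1``.
    """

    mu0: np.ndarray
    mu1: np.ndarray
    Sigma: np.ndarray
    pi1: float

    def __post_init__(self):
        object.__setattr__(self, "mu0", np.asarray(self.mu0, dtype=np.float64))
        object.__setattr__(self, "mu1", np.asarray(self.mu1, dtype=np.float64))
        object.__setattr__(self, "Sigma", np.asarray(self.Sigma, dtype=np.float64))
        object.__setattr__(self, "pi1", float(self.pi1))
        n = self.mu0.shape[0]
        if self.mu0.ndim != 1 or self.mu1.shape != (n,):
            raise DimensionError("mu0 and mu1 must be 1-D vectors of equal length")
        if self.Sigma.shape != (n, n):
            raise DimensionError(f"Sigma must be {n}x{n}, got {self.Sigma.shape}")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10, rtol=1e-10):
            raise ConfigError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as exc:
            raise ConfigError("Sigma must be positive definite") from exc
        if not 0.0 < self.pi1 < 1.0:
            raise ConfigError(f"pi1 must lie in (0, 1), got {self.pi1}")

    @property
    def n(self) -> int:
        return self.mu0.shape[0]

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    def to_json(self, path=None):
        d = {
            "mu0": self.mu0.tolist(),
            "mu1": self.mu1.tolist(),
            "Sigma": self.Sigma.tolist(),
            "pi1": self.pi1,
        }
        if path is None:
            return json.dumps(d)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
            fh.write("\n")
        return None

    @classmethod
    def from_json(cls, source) -> "ClassStatistics":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(mu0=d["mu0"], mu1=d["mu1"], Sigma=d["Sigma"], pi1=d["pi1"])


@dataclass(frozen=True)
class OfflineSolution:
    """Closed-form LDA optimum and the accuracy of its decision rule."""

    w_opt: np.ndarray
    b_opt: float
    bayes_accuracy: float


def lda_objective(w, stats: ClassStatistics) -> float:
    """``L(w) = -w.(mu0 - mu1) + 1/2 w^T Sigma w`` (convex; minimised by w_opt)."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (stats.n,):
        raise DimensionError(f"w has shape {w.shape}, expected ({stats.n},)")
    return float(-w @ (stats.mu0 - stats.mu1) + 0.5 * w @ stats.Sigma @ w)


def _checked_solve(Sigma: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    eigvals = np.linalg.eigvalsh(Sigma)
    lam_min, lam_max = eigvals[0], eigvals[-1]
    if lam_min <= 0 or lam_max / lam_min > CONDITION_LIMIT:
        cond = math.inf if lam_min <= 0 else lam_max / lam_min
        raise IllConditionedError(
            f"covariance is singular or ill-conditioned (condition number {cond:.3e}, "
            f"limit {CONDITION_LIMIT:.0e})"
        )
    return cho_solve(cho_factor(Sigma, lower=True), rhs)


def optimal_solution(stats: ClassStatistics) -> OfflineSolution:
    """Closed-form ``(w_opt, b_opt)`` and the Bayes accuracy of that boundary.

    The projected inputs ``c = w_opt . x`` are Gaussian within each class with
    means ``w_opt . mu_i`` and shared variance ``w_opt^T Sigma w_opt``, so

        P(correct) = pi0 P(G0 > b_opt) + pi1 P(G1 < b_opt)

    in closed form from Gaussian tail probabilities (ties ``c == b`` are
    classified as class 1, matching the strict ``z > 0`` prediction rule; they
    carry zero probability here).
    """
    w = _checked_solve(stats.Sigma, stats.mu0 - stats.mu1)
    b = float(0.5 * w @ (stats.mu0 + stats.mu1) + math.log(stats.pi1 / stats.pi0))
    m0 = float(w @ stats.mu0)
    m1 = float(w @ stats.mu1)
    s2 = float(w @ stats.Sigma @ w)
    if s2 <= 0.0:
        # mu0 == mu1 degenerates to a constant projection: predict by prior.
        acc = stats.pi0 if -b > 0 else stats.pi1
    else:
        s = math.sqrt(s2)
        acc = stats.pi0 * float(ndtr((m0 - b) / s)) + stats.pi1 * float(ndtr((b - m1) / s))
    return OfflineSolution(w_opt=w, b_opt=b, bayes_accuracy=acc)


def gradient_step(w, stats: ClassStatistics, eta: float):
    """One batch gradient-descent step on L(w).

    Converges for ``eta < 2 / lambda_max(Sigma)`` (not enforced).
    """
    w = np.asarray(w, dtype=np.float64)
    return w + eta * (stats.mu0 - stats.mu1 - stats.Sigma @ w)


def gradient_flow(t: float, w0, stats: ClassStatistics):
    """Closed-form solution of ``w'(t) = mu0 - mu1 - Sigma w(t)``.

    ``w(t) = e^{-Sigma t} w0 + (I - e^{-Sigma t}) Sigma^{-1}(mu0 - mu1)``,
    computed through the eigendecomposition of the symmetric matrix Sigma;
    converges exponentially to ``w_opt``.
    """
    if t < 0:
        raise ConfigError(f"t must be >= 0, got {t}")
    w0 = np.asarray(w0, dtype=np.float64)
    w_opt = _checked_solve(stats.Sigma, stats.mu0 - stats.mu1)
    lam, V = eigh(stats.Sigma)
    decay = np.exp(-lam * t)
    E = (V * decay) @ V.T
    return E @ w0 + (np.eye(stats.n) - E) @ w_opt
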