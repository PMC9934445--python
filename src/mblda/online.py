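"""Online imbalanced-LDA plasticity model of a mushroom body compartment.

The mushroom body output neuron (MBON) is modelled as a thresholded linear
readout of the Kenyon-cell (KC) population activity ``x_t``:

    c_t = w . x_t,     z_t = max(c_t - b, 0)

where ``w`` are the KC->MBON synaptic strengths and ``b`` is the MBON firing
threshold.  ``z_t > 0`` is read as the prediction "no unconditioned stimulus"
(y = 0) and ``z_t = 0`` as the prediction that the stimulus is present
(y = 1).  Learning is gated by the dopamine neuron (DAN) label ``y_t``:

* ``y_t = 0`` (DAN silent) — a homeostatic rule updates running estimates of
  the neutral-odor mean ``mu0`` and of the mean MBON input ``zeta``, then
  moves the weights by ``eta * (mu0 - (c - zeta) * (x - mu0))``.  Averaged
  over neutral odors this equals ``eta * (mu0 - Sigma w)``, so with the DAN
  silent the weights equilibrate at ``Sigma^{-1} mu0``.
* ``y_t = 1`` (DAN active) — a one-sided depression ``dw = -eta * ell * x``
  where ``ell`` counts the time steps elapsed since the previous DAN event.
  The conditional mean of ``ell`` estimates ``1/pi1`` (the inverse class-1
  frequency), which rebalances the temporally sparse depression events
  against the ever-present homeostatic drive.  The update never reads the
  MBON output ``z`` or threshold ``b``.

Two published variants are available: ``fixed_ell`` replaces the elapsed-time
counter by a constant ``ell*``, and ``graded_dan`` admits a nonnegative
graded DAN signal ``y`` that scales the depression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import ConfigError, DimensionError
from .trace import Trace

__all__ = [
    "CompartmentState",
    "LearningConfig",
    "StepOutput",
    "VARIANTS",
    "learning_rate",
    "mbon_output",
    "homeostatic_step",
    "dan_step",
    "step",
    "run_online",
]

VARIANTS = ("standard", "fixed_ell", "graded_dan")

_VARIANT_CODES = {
    "standard": _kernels.VARIANT_STANDARD,
    "fixed_ell": _kernels.VARIANT_FIXED_ELL,
    "graded_dan": _kernels.VARIANT_GRADED_DAN,
}


def _as_vector(x, n=None, name="x"):
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise DimensionError(f"{name} has dimension {arr.shape[0]}, expected {n}")
    return arr


@dataclass
class CompartmentState:
    """Full learnable and running state of one MBON compartment.

    Attributes
    ----------
    w : ndarray
        KC->MBON synaptic weights (unconstrained sign), length ``n``.
    mu0_hat : ndarray
        Running estimate of the neutral-odor mean activity, length ``n``.
    b : float
        MBON firing threshold.
    zeta_hat : float
        Running estimate of the mean MBON input under ``y = 0``.
    ell : int
        Time steps elapsed since the last DAN event; ``ell >= 1`` always and
        ``ell == 1`` immediately after a DAN event.
    t : int
        Global step count.
    """

    w: np.ndarray
    mu0_hat: np.ndarray
    b: float = 0.0
    zeta_hat: float = 0.0
    ell: int = 1
    t: int = 0

    def __post_init__(self):
        self.w = _as_vector(self.w, name="w")
        self.mu0_hat = _as_vector(self.mu0_hat, self.w.shape[0], name="mu0_hat")
        self.b = float(self.b)
        self.zeta_hat = float(self.zeta_hat)
        self.ell = int(self.ell)
        self.t = int(self.t)
        if self.ell < 1:
            raise ConfigError(f"ell must be >= 1, got {self.ell}")
        if self.t < 0:
            raise ConfigError(f"t must be >= 0, got {self.t}")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @classmethod
    def zeros(cls, n: int) -> "CompartmentState":
        """Deterministic default: zero weights, zero statistics."""
        return cls(w=np.zeros(n), mu0_hat=np.zeros(n))

    @classmethod
    def random_init(cls, n: int, sigma: float, seed=None) -> "CompartmentState":
        """Gaussian(0, sigma^2) initial weights; statistics start at zero."""
        rng = np.random.default_rng(seed)
        return cls(w=sigma * rng.standard_normal(n), mu0_hat=np.zeros(n))

    def copy(self) -> "CompartmentState":
        return CompartmentState(
            w=self.w.copy(),
            mu0_hat=self.mu0_hat.copy(),
            b=self.b,
            zeta_hat=self.zeta_hat,
            ell=self.ell,
            t=self.t,
        )

    # -- flat key-value checkpointing (round-trip exact for doubles) --------
    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "mu0_hat": self.mu0_hat.tolist(),
            "b": self.b,
            "zeta_hat": self.zeta_hat,
            "ell": self.ell,
            "t": self.t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentState":
        return cls(
            w=np.asarray(d["w"], dtype=np.float64),
            mu0_hat=np.asarray(d["mu0_hat"], dtype=np.float64),
            b=d["b"],
            zeta_hat=d["zeta_hat"],
            ell=d["ell"],
            t=d["t"],
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load_json(cls, path) -> "CompartmentState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LearningConfig:
    """Learning-rate schedule and variant selector.

    ``eta_t = eta0 / (1 + gamma * t)`` evaluated at the post-increment step
    index ``t = 1, 2, ...``.  Defaults are the grid-search optimum for the
    two-Gaussian stream (``eta0 = 0.1``, ``gamma = 1e-3``).

    ``eta0 = 0`` is allowed and freezes the weights while the threshold and
    running statistics continue to evolve.
    """

    eta0: float = 0.1
    gamma: float = 1e-3
    variant: str = "standard"
    ell_star: float | None = None
    fixed_ell_bias: bool = True
    init_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.eta0 < 0:
            raise ConfigError(f"eta0 must be >= 0, got {self.eta0}")
        if self.gamma < 0:
            raise ConfigError(f"gamma must be >= 0, got {self.gamma}")
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "fixed_ell":
            if self.ell_star is None or self.ell_star <= 0:
                raise ConfigError("fixed_ell variant requires ell_star > 0")
        if self.init_sigma < 0:
            raise ConfigError("init_sigma must be >= 0")


@dataclass(frozen=True)
class StepOutput:
    """MBON response to one KC activity pattern."""

    c: float
    z: float

    @property
    def predicted_label(self) -> int:
        # z == 0 is the prediction that the unconditioned stimulus is present.
        return 0 if self.z > 0 else 1


def learning_rate(t: int, config: LearningConfig) -> float:
    """Decaying schedule ``eta_t = eta0 / (1 + gamma t)`` for ``t >= 1``."""
    if t < 1:
        raise ConfigError(f"step index t must be >= 1, got {t}")
    return config.eta0 / (1.0 + config.gamma * t)


def mbon_output(state: CompartmentState, x) -> StepOutput:
    """MBON input ``c = w.x`` and rectified output ``z = max(c - b, 0)``."""
    x = _as_vector(x, state.n)
    c = float(np.dot(state.w, x))
    z = c - state.b
    if z < 0.0:
        z = 0.0
    return StepOutput(c=c, z=z)


def homeostatic_step(state: CompartmentState, x, eta: float) -> CompartmentState:
    """One DAN-silent (``y = 0``) update; returns a new state.

    In printed order: advance ``t``; update the running neutral-odor mean and
    the running mean input ``zeta`` with ``1/t`` steps; pull ``b`` toward
    ``c/2``; move ``w`` by ``eta * (mu0 - (c - zeta) * (x - mu0))`` using the
    already-updated statistics and the pre-update ``c``; increment ``ell``.
    """
    x = _as_vector(x, state.n)
    c = float(np.dot(state.w, x))
    t = state.t + 1
    inv_t = 1.0 / t
    mu0 = state.mu0_hat + inv_t * (x - state.mu0_hat)
    zeta = state.zeta_hat + inv_t * (c - state.zeta_hat)
    b = state.b + inv_t * (0.5 * c - state.b)
    cz = c - zeta
    w = state.w + eta * (mu0 - cz * (x - mu0))
    return CompartmentState(w=w, mu0_hat=mu0, b=b, zeta_hat=zeta, ell=state.ell + 1, t=t)


def dan_step(
    state: CompartmentState,
    x,
    eta: float,
    *,
    ell_weight: float | None = None,
    ell_bias: float | None = None,
    y_scale: float = 1.0,
) -> CompartmentState:
    """One DAN-active (``y = 1``) update; returns a new state.

    The weight update ``w -= eta * ell * x`` is independent of the MBON
    output ``z`` and threshold ``b``.  The keyword overrides implement the
    fixed-``ell*`` and graded-DAN variants; by default both updates use the
    state's elapsed-time counter and ``y_scale = 1``.
    """
    x = _as_vector(x, state.n)
    c = float(np.dot(state.w, x))
    t = state.t + 1
    inv_t = 1.0 / t
    ell_w = float(state.ell) if ell_weight is None else float(ell_weight)
    ell_b = float(state.ell) if ell_bias is None else float(ell_bias)
    b = state.b + inv_t * (0.5 * ell_b * c - math.log(ell_b) - state.b)
    scale = eta * ell_w
    if y_scale != 1.0:
        scale = scale * y_scale
    w = state.w - scale * x
    return CompartmentState(w=w, mu0_hat=state.mu0_hat.copy(), b=b, zeta_hat=state.zeta_hat, ell=1, t=t)


def _validate_label(y, variant: str) -> float:
    yv = float(y)
    if variant == "graded_dan":
        if yv < 0:
            raise ConfigError(f"graded_dan labels must be nonnegative, got {y}")
        return yv
    if yv not in (0.0, 1.0):
        raise ConfigError(f"labels must be 0 or 1 for variant {variant!r}, got {y}")
    return yv


def step(state: CompartmentState, x, y, config: LearningConfig | None = None):
    """One full update: output from the pre-update state, then plasticity.

    Returns ``(new_state, StepOutput)``.  The input state is never mutated.
    """
    if config is None:
        config = LearningConfig()
    x = _as_vector(x, state.n)
    yv = _validate_label(y, config.variant)
    out = mbon_output(state, x)
    eta = learning_rate(state.t + 1, config)
    if yv == 0.0:
        new = homeostatic_step(state, x, eta)
    elif config.variant == "fixed_ell":
        ell_b = config.ell_star if config.fixed_ell_bias else None
        new = dan_step(state, x, eta, ell_weight=config.ell_star, ell_bias=ell_b)
    elif config.variant == "graded_dan":
        new = dan_step(state, x, eta, y_scale=yv)
    else:
        new = dan_step(state, x, eta)
    return new, out


def _coerce_stream(stream):
    """Accept an (X, Y) array pair or an iterable of (x, y) pairs."""
    if isinstance(stream, tuple) and len(stream) == 2:
        X = np.asarray(stream[0], dtype=np.float64)
        Y = np.asarray(stream[1], dtype=np.float64)
        if X.size == 0 and Y.size == 0:
            return np.empty((0, 0)), np.empty((0,))
        if X.ndim == 2 and Y.ndim == 1 and X.shape[0] == Y.shape[0]:
            return np.ascontiguousarray(X), np.ascontiguousarray(Y)
    pairs = list(stream)
    if not pairs:
        return np.empty((0, 0)), np.empty((0,))
    X = np.ascontiguousarray([np.asarray(x, dtype=np.float64) for x, _ in pairs])
    Y = np.ascontiguousarray([float(y) for _, y in pairs])
    return X, Y


def run_online(stream, config: LearningConfig | None = None, init: CompartmentState | None = None):
    """Run the online algorithm over a labelled stream.

    Parameters
    ----------
    stream : (X, Y) pair of arrays, or iterable of (x, y) pairs
        ``X`` has one feature vector per row; ``Y`` holds the DAN labels.
    config : LearningConfig, optional
    init : CompartmentState, optional
        Defaults to zero weights (or Gaussian weights when
        ``config.init_sigma > 0``, seeded by ``config.seed``).

    Returns
    -------
    (CompartmentState, Trace)
        Final state and the per-step record of ``(c, z, y, ell, eta)``,
        where ``ell`` is the elapsed-time counter in effect at each step.
    """
    if config is None:
        config = LearningConfig()
    X, Y = _coerce_stream(stream)
    T = X.shape[0]
    if T == 0:
        raise ConfigError("stream is empty")
    n = X.shape[1]
    if init is None:
        if config.init_sigma > 0:
            init = CompartmentState.random_init(n, config.init_sigma, config.seed)
        else:
            init = CompartmentState.zeros(n)
    if init.n != n:
        raise DimensionError(f"state dimension {init.n} != stream dimension {n}")
    if config.variant == "graded_dan":
        if np.any(Y < 0):
            raise ConfigError("graded_dan labels must be nonnegative")
    elif not np.all((Y == 0.0) | (Y == 1.0)):
        bad = Y[(Y != 0.0) & (Y != 1.0)][0]
        raise ConfigError(f"labels must be 0 or 1 for variant {config.variant!r}, got {bad}")

    w = init.w.copy()
    mu0 = init.mu0_hat.copy()
    c_out = np.empty(T)
    z_out = np.empty(T)
    ell_out = np.empty(T, dtype=np.int64)
    eta_out = np.empty(T)
    ell_star = float(config.ell_star) if config.ell_star is not None else 1.0
    b, zeta, ell, t = _kernels.run_stream(
        X,
        Y,
        w,
        mu0,
        float(init.b),
        float(init.zeta_hat),
        np.int64(init.ell),
        np.int64(init.t),
        float(config.eta0),
        float(config.gamma),
        _VARIANT_CODES[config.variant],
        ell_star,
        bool(config.fixed_ell_bias),
        c_out,
        z_out,
        ell_out,
        eta_out,
    )
    final = CompartmentState(w=w, mu0_hat=mu0, b=float(b), zeta_hat=float(zeta), ell=int(ell), t=int(t))
    trace = Trace(c=c_out, z=z_out, y=Y.copy(), ell=ell_out, eta=eta_out)
    return final, trace
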