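"""Synthetic labelled streams and delimited-text stream I/O.

Two generators emulate the statistical structure of the model's test beds:

* a two-class equal-covariance Gaussian stream in low dimension, with the
  class-1 (DAN-active) steps scheduled by a Bernoulli, strictly periodic, or
  high-variance irregular process; and
* a Kenyon-cell surrogate: a small set of fixed sparse odor templates over
  ~124 units, each presentation corrupted by isotropic Gaussian noise with
  covariance ``epsilon * I`` (``epsilon = 0.01``), with a subset of odors
  designated class 1 so that ``pi1 = |class-1 odors| / n_odors``.

All generators are pure functions of their spec (seed included): equal specs
give bit-equal outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, StreamFormatError
from .offline import ClassStatistics

__all__ = [
    "GaussianStreamSpec",
    "KCSurrogateSpec",
    "default_gaussian_stats",
    "generate_gaussian_stream",
    "default_templates",
    "generate_kc_surrogate_stream",
    "read_stream_csv",
    "write_stream_csv",
]

SCHEDULES = ("bernoulli", "periodic", "irregular")


def default_gaussian_stats(pi1: float = 0.1) -> ClassStatistics:
    """Default overlapping two-Gaussian geometry.

    ``mu0 = (1, 0)``, ``mu1 = (-1, 0)``, ``Sigma = I``: Mahalanobis
    separation 2, so the optimal accuracy is below 1 for every prior.
    """
    return ClassStatistics(mu0=[1.0, 0.0], mu1=[-1.0, 0.0], Sigma=np.eye(2), pi1=pi1)


@dataclass(frozen=True, eq=False)
class GaussianStreamSpec:
    """Parameters of a synthetic two-Gaussian labelled stream.

    ``pi1`` defaults to ``stats.pi1``; ``short_gap_prob`` only affects the
    irregular schedule (see :func:`generate_gaussian_stream`).
    """

    stats: ClassStatistics
    T: int = 100_000
    pi1: float | None = None
    schedule: str = "bernoulli"
    seed: int = 0
    short_gap_prob: float = 0.5

    def __post_init__(self):
        if self.T < 1:
            raise ConfigError(f"T must be >= 1, got {self.T}")
        if self.schedule not in SCHEDULES:
            raise ConfigError(f"schedule must be one of {SCHEDULES}, got {self.schedule!r}")
        p1 = self.class1_frequency
        if not 0.0 < p1 < 1.0:
            raise ConfigError(f"pi1 must lie in (0, 1), got {p1}")
        if not 0.0 < self.short_gap_prob < 1.0:
            raise ConfigError("short_gap_prob must lie in (0, 1)")

    @property
    def class1_frequency(self) -> float:
        return self.stats.pi1 if self.pi1 is None else float(self.pi1)

    def with_seed(self, seed: int) -> "GaussianStreamSpec":
        return replace(self, seed=seed)


def _periodic_labels(T: int, pi1: float) -> np.ndarray:
    period = round(1.0 / pi1)
    if period < 1 or abs(1.0 / pi1 - period) > 1e-6:
        raise ConfigError(
            f"periodic schedule requires 1/pi1 to be an integer period, got 1/pi1 = {1.0 / pi1}"
        )
    y = np.zeros(T)
    y[period - 1 :: period] = 1.0
    return y


def _irregular_labels(T: int, pi1: float, short_gap_prob: float, rng) -> np.ndarray:
    """High-variance gaps with mean pinned to ``1/pi1``.

    Each inter-event gap is 1 with probability ``short_gap_prob`` and
    ``1 + Geometric(p)`` otherwise, with ``p`` chosen so the mixture mean is
    exactly ``1/pi1``.  Requires ``pi1 <= 0.5`` (mean gap > 1).
    """
    m = 1.0 / pi1
    if m <= 1.0 + 1e-12 or pi1 > 0.5:
        raise ConfigError("irregular schedule requires pi1 <= 0.5")
    mean_long = (m - 1.0) / (1.0 - short_gap_prob)
    p_geo = 1.0 / mean_long
    if p_geo > 1.0:
        raise ConfigError("irregular schedule: mixture mean not attainable; lower short_gap_prob")
    y = np.zeros(T)
    pos = 0
    while True:
        batch = max(64, int(2 * T * pi1))
        short = rng.random(batch) < short_gap_prob
        gaps = np.where(short, 1, 1 + rng.geometric(p_geo, size=batch))
        for g in gaps:
            pos += int(g)
            if pos > T:
                return y
            y[pos - 1] = 1.0


def generate_gaussian_stream(spec: GaussianStreamSpec):
    """Generate ``(X, Y)``: ``x_t ~ N(mu_{y_t}, Sigma)`` under the schedule."""
    rng = np.random.default_rng(spec.seed)
    pi1 = spec.class1_frequency
    if spec.schedule == "bernoulli":
        Y = (rng.random(spec.T) < pi1).astype(np.float64)
    elif spec.schedule == "periodic":
        Y = _periodic_labels(spec.T, pi1)
    else:
        Y = _irregular_labels(spec.T, pi1, spec.short_gap_prob, rng)
    stats = spec.stats
    L = np.linalg.cholesky(stats.Sigma)
    noise = rng.standard_normal((spec.T, stats.n)) @ L.T
    means = np.where(Y[:, None] == 1.0, stats.mu1, stats.mu0)
    return means + noise, Y


@dataclass(frozen=True, eq=False)
class KCSurrogateSpec:
    """Parameters of the Kenyon-cell surrogate stream.

    ``templates`` may be supplied directly (``n_odors x n_units``,
    nonnegative); otherwise sparse templates are drawn from
    :func:`default_templates` using ``seed``.
    """

    n_units: int = 124
    n_odors: int = 7
    templates: np.ndarray | None = None
    sparsity: float = 0.1
    epsilon: float = 0.01
    class1_odors: frozenset = frozenset({0})
    T: int = 100_000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "class1_odors", frozenset(int(o) for o in self.class1_odors))
        if self.templates is not None:
            tpl = np.asarray(self.templates, dtype=np.float64)
            if tpl.shape != (self.n_odors, self.n_units):
                raise ConfigError(
                    f"templates must be {self.n_odors}x{self.n_units}, got {tpl.shape}"
                )
            if np.any(tpl < 0):
                raise ConfigError("templates must be nonnegative")
            object.__setattr__(self, "templates", tpl)
        if self.epsilon < 0:
            raise ConfigError(f"epsilon must be >= 0, got {self.epsilon}")
        if not 0.0 < self.sparsity <= 1.0:
            raise ConfigError(f"sparsity must lie in (0, 1], got {self.sparsity}")
        if self.T < 1:
            raise ConfigError(f"T must be >= 1, got {self.T}")
        if not self.class1_odors:
            raise ConfigError("class1_odors must be nonempty")
        if not self.class1_odors < set(range(self.n_odors)):
            raise ConfigError(
                "class1_odors must be a strict subset of range(n_odors) "
                f"(got {sorted(self.class1_odors)} of {self.n_odors} odors)"
            )

    @property
    def pi1(self) -> float:
        return len(self.class1_odors) / self.n_odors

    def resolved_templates(self) -> np.ndarray:
        if self.templates is not None:
            return self.templates
        return default_templates(self.n_units, self.n_odors, self.sparsity, self.seed)

    def with_seed(self, seed: int) -> "KCSurrogateSpec":
        """New spec with a different stream seed but the SAME templates."""
        return replace(self, templates=self.resolved_templates(), seed=seed)


def default_templates(n_units: int, n_odors: int, sparsity: float, seed) -> np.ndarray:
    """Sparse nonnegative odor templates.

    Each odor activates ``round(sparsity * n_units)`` units chosen uniformly
    without replacement (supports drawn independently across odors);
    active magnitudes are i.i.d. Gamma(shape 2, scale 0.5) — mean 1,
    strictly positive.  Expected pairwise support overlap is
    ``sparsity^2 * n_units``.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ConfigError(f"sparsity must lie in (0, 1], got {sparsity}")
    rng = np.random.default_rng(seed)
    k = max(1, round(sparsity * n_units))
    templates = np.zeros((n_odors, n_units))
    for o in range(n_odors):
        support = rng.choice(n_units, size=k, replace=False)
        templates[o, support] = rng.gamma(shape=2.0, scale=0.5, size=k)
    return templates


def generate_kc_surrogate_stream(spec: KCSurrogateSpec, return_odors: bool = False):
    """Generate ``(X, Y)`` (optionally ``(X, Y, odors)``).

    Each step presents an odor chosen uniformly at random; the emitted
    pattern is the odor's template plus ``N(0, epsilon I)`` noise, and
    ``y = 1`` iff the odor is in ``class1_odors``.
    """
    templates = spec.resolved_templates()
    rng = np.random.default_rng(spec.seed)
    odors = rng.integers(0, spec.n_odors, size=spec.T)
    X = templates[odors]
    if spec.epsilon > 0:
        X = X + np.sqrt(spec.epsilon) * rng.standard_normal((spec.T, spec.n_units))
    else:
        X = X.copy()
    Y = np.isin(odors, list(spec.class1_odors)).astype(np.float64)
    if return_odors:
        return X, Y, odors
    return X, Y


# ---------------------------------------------------------------------------
# Delimited-text stream I/O
# ---------------------------------------------------------------------------


def _delimiter_for(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_stream_csv(path, delimiter=None, strict_labels: bool = True):
    """Read a labelled stream: n feature columns plus a final label column.

    A non-numeric first row is treated as a header.  Malformed rows,
    inconsistent widths, and (under ``strict_labels``) labels outside {0, 1}
    raise :class:`StreamFormatError` naming the line; with
    ``strict_labels=False`` any nonnegative label is accepted (graded DAN).
    """
    delim = _delimiter_for(path, delimiter)
    X_rows, labels = [], []
    width = None
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                values = [float(cell) for cell in row]
            except ValueError:
                if lineno == 1:
                    continue  # header
                bad = next(cell for cell in row if not _is_number(cell))
                raise StreamFormatError(f"non-numeric field {bad!r}", line=lineno) from None
            if len(values) < 2:
                raise StreamFormatError(
                    "need at least one feature column plus a label column", line=lineno
                )
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise StreamFormatError(
                    f"row has {len(values)} fields, expected {width}", line=lineno
                )
            label = values[-1]
            if strict_labels and label not in (0.0, 1.0):
                raise StreamFormatError(f"label must be 0 or 1, got {label}", line=lineno)
            if not strict_labels and label < 0:
                raise StreamFormatError(f"label must be nonnegative, got {label}", line=lineno)
            X_rows.append(values[:-1])
            labels.append(label)
    if not X_rows:
        raise StreamFormatError(f"no data rows in {path}")
    return np.asarray(X_rows, dtype=np.float64), np.asarray(labels, dtype=np.float64)


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_stream_csv(stream, path, delimiter=None, header=None) -> None:
    """Write a labelled stream; floats use shortest round-trip reprs so a
    write-then-read cycle is bit-exact."""
    from .online import _coerce_stream

    X, Y = _coerce_stream(stream)
    delim = _delimiter_for(path, delimiter)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if header is not None:
            writer.writerow(header)
        for x, y in zip(X, Y):
            writer.writerow([repr(float(v)) for v in x] + [repr(float(y))])
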