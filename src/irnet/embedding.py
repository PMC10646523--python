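"""Phase-space reconstruction from scalar time series.

Provides standardization, time-delay embedding, and the two classical
heuristics for choosing embedding parameters: the first minimum of the
average mutual information (AMI) profile for the delay, and the false
nearest neighbour (FNN) fraction for the dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingSpec",
    "StateTrajectory",
    "standardize",
    "delay_embed",
    "ami_profile",
    "first_minimum_lag",
    "fnn_profile",
    "select_dim",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: lag (samples), dimension, standardization flag."""

    lag: int
    dim: int
    standardized: bool = True

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")

    def n_points(self, n_samples: int) -> int:
        """Number of embedded state vectors obtainable from ``n_samples``."""
        return n_samples - (self.dim - 1) * self.lag

    def min_length(self) -> int:
        """Shortest series that still yields two state vectors."""
        return (self.dim - 1) * self.lag + 2


@dataclass
class StateTrajectory:
    """A trajectory of state vectors in reconstructed or native phase space.

    ``points`` is an (N', m) array; ``spec`` is the :class:`EmbeddingSpec`
    used to build it, or ``None`` for trajectories given directly in their
    native state space (e.g. position/velocity pairs of a simulated
    oscillator).
    """

    points: np.ndarray
    spec: EmbeddingSpec | None = None
    source_length: int = field(default=0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim == 1:
            self.points = self.points[:, None]
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array of state vectors")
        if not np.isfinite(self.points).all():
            raise ValueError("state trajectory contains non-finite values")
        if self.source_length == 0:
            self.source_length = len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def standardize(series: np.ndarray) -> np.ndarray:
    """Scale to zero mean and unit sample standard deviation (denominator N-1).

    Raises ``ValueError`` for constant series, whose variance is zero.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1-D series")
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant series (zero variance)")
    return (x - x.mean()) / sd


def delay_embed(series: np.ndarray, spec: EmbeddingSpec) -> StateTrajectory:
    """Time-delay embedding: row i is (s_i, s_{i+lag}, ..., s_{i+(dim-1)lag})."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("delay_embed expects a 1-D series")
    n = spec.n_points(len(x))
    if n < 2:
        raise ValueError(
            f"series of length {len(x)} too short for lag={spec.lag}, "
            f"dim={spec.dim}; minimum length is {spec.min_length()}"
        )
    if spec.standardized:
        x = standardize(x)
    cols = [x[i * spec.lag : i * spec.lag + n] for i in range(spec.dim)]
    return StateTrajectory(np.column_stack(cols), spec=spec, source_length=len(x))


def ami_profile(series: np.ndarray, max_lag: int, n_bins: int = 32) -> np.ndarray:
    """Average mutual information (nats) of (s_t, s_{t+k}) for k = 0 .. max_lag.

    Uses an equal-width 2-D histogram estimator. Entry 0 is the marginal
    entropy estimate (self-information at zero lag).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be below half the series length")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    edges[-1] += 1e-12  # include the maximum in the last bin
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a = x[: n - k] if k else x
        b = x[k:] if k else x
        h, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        p = h / h.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        out[k] = float((p[nz] * np.log(p[nz] / np.outer(px, py)[nz])).sum())
    return out


def first_minimum_lag(profile: np.ndarray) -> int:
    """Lag of the first strict local minimum of an AMI profile.

    Falls back (with a warning) to the global minimum when the profile is
    monotone and has no interior minimum.
    """
    p = np.asarray(profile, dtype=float)
    for k in range(1, len(p) - 1):
        if p[k] < p[k - 1] and p[k] < p[k + 1]:
            return k
    warnings.warn(
        "AMI profile has no strict local minimum; using the global minimum",
        stacklevel=2,
    )
    return int(np.argmin(p[1:]) + 1) if len(p) > 1 else 0


def fnn_profile(
    series: np.ndarray,
    lag: int,
    max_dim: int,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> np.ndarray:
    """Fraction of false nearest neighbours for dimensions 1 .. max_dim.

    The classic criterion: a point's nearest neighbour in dimension m is
    false when the extra (m+1)-th coordinate increases their distance by a
    factor above ``r_tol``, or moves them further apart than ``a_tol`` times
    the series standard deviation. Profiles are truncated with a warning when
    the series is too short for the larger dimensions.
    """
    x = standardize(np.asarray(series, dtype=float))
    sd = x.std(ddof=1)  # 1.0 after standardization; kept explicit
    fractions = []
    for m in range(1, max_dim + 1):
        n = len(x) - m * lag  # need the (m+1)-th coordinate for the test
        if n < 2:
            warnings.warn(
                f"series too short for FNN at dim {m}; profile truncated",
                stacklevel=2,
            )
            break
        emb = np.column_stack([x[i * lag : i * lag + n] for i in range(m)])
        extra = x[m * lag : m * lag + n]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        d, j = dist[:, 1], idx[:, 1]
        gap = np.abs(extra - extra[j])
        d_new = np.sqrt(d**2 + gap**2)
        # multiplicative form of the ratio test; the absolute floor keeps
        # coincident points (exact recurrences, d and gap at round-off level)
        # from counting as false neighbours
        false = ((gap > r_tol * d) & (gap > 1e-10 * sd)) | (d_new > a_tol * sd)
        fractions.append(false.mean())
    return np.asarray(fractions)


def select_dim(profile: np.ndarray, threshold: float = 0.01) -> int:
    """Smallest embedding dimension whose FNN fraction falls below ``threshold``.

    Raises ``ValueError`` when no dimension in the profile qualifies.
    """
    p = np.asarray(profile, dtype=float)
    below = np.nonzero(p < threshold)[0]
    if len(below) == 0:
        raise ValueError(
            f"no dimension up to {len(p)} reaches an FNN fraction below {threshold}"
        )
    return int(below[0] + 1)
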