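"""Distance matrices, threshold calibration, and recurrence matrices.

A recurrence plot marks pairs of time points whose state-space distance
falls below a threshold epsilon. Auto-recurrence compares a trajectory with
itself; cross-recurrence compares the states of one system with those of
another embedded in a shared state space. Thresholds are usually calibrated
so that a predetermined fraction of eligible cells recurs (the recurrence
rate, RR): for auto plots the eligible population is the strict upper
triangle (the trivial line of identity is excluded), for cross plots it is
every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import StateTrajectory

__all__ = [
    "RecurrencePlot",
    "distance_matrix",
    "threshold_for_rr",
    "auto_recurrence",
    "cross_recurrence",
]

_NORMS = {"euclidean": "euclidean", "chebyshev": "chebyshev"}


@dataclass
class RecurrencePlot:
    """Binary recurrence matrix with its threshold and realized rate.

    ``kind`` is ``"auto"`` (square, symmetric, diagonal kept in the matrix
    but not counted in the rate) or ``"cross"`` (generally asymmetric; its
    transpose is the cross plot with the roles of the systems swapped).
    """

    matrix: np.ndarray
    kind: str
    epsilon: float
    realized_rr: float
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("recurrence matrix must be 2-D")
        if self.kind not in ("auto", "cross"):
            raise ValueError("kind must be 'auto' or 'cross'")
        if self.kind == "auto":
            if m.shape[0] != m.shape[1]:
                raise ValueError("auto-recurrence matrix must be square")
            if not np.array_equal(m, m.T):
                raise ValueError("auto-recurrence matrix must be symmetric")
        self.matrix = m.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def transpose(self) -> "RecurrencePlot":
        """The cross plot with the two systems' roles swapped (CR^YX = (CR^XY)^T)."""
        if self.kind != "cross":
            raise ValueError("transpose is only meaningful for cross plots")
        return RecurrencePlot(
            self.matrix.T, "cross", self.epsilon, self.realized_rr, self.norm
        )

    def to_coordinates(self):
        """(i, j) index pairs of recurrent cells, suitable for CSV export."""
        i, j = np.nonzero(self.matrix)
        return np.column_stack([i, j])

    def save_coordinates_csv(self, path) -> None:
        np.savetxt(
            path, self.to_coordinates(), fmt="%d", delimiter=",", header="i,j",
            comments="",
        )

    def save_matrix_market(self, path) -> None:
        from scipy import io, sparse

        io.mmwrite(str(path), sparse.coo_matrix(self.matrix))


def _points(a) -> np.ndarray:
    if isinstance(a, StateTrajectory):
        return a.points
    arr = np.asarray(a, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def distance_matrix(a, b=None, norm: str = "euclidean") -> np.ndarray:
    """Pairwise distances D_ij = ||a_i - b_j|| (b = a when absent).

    The auto case (``b is None``) is made exactly symmetric with a zero
    diagonal, which floating-point round-off would otherwise not guarantee.
    """
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}; choose from {sorted(_NORMS)}")
    pa = _points(a)
    if b is None:
        d = cdist(pa, pa, metric=_NORMS[norm])
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        return d
    pb = _points(b)
    if pa.shape[1] != pb.shape[1]:
        raise ValueError(
            f"dimension mismatch: {pa.shape[1]} vs {pb.shape[1]} coordinates"
        )
    return cdist(pa, pb, metric=_NORMS[norm])


def _eligible(distances: np.ndarray, kind: str) -> np.ndarray:
    if kind == "auto":
        iu = np.triu_indices(distances.shape[0], k=1)
        return distances[iu]
    return distances.ravel()


def threshold_for_rr(distances: np.ndarray, target_rr: float, kind: str) -> float:
    """Distance threshold whose Heaviside application yields ``target_rr``.

    Returns the linear-interpolation quantile of the eligible distance
    population (auto: strict upper triangle; cross: all cells). The realized
    rate after applying Theta(eps - d) with a strict inequality is within one
    cell count of the target.
    """
    if not 0 < target_rr < 1:
        raise ValueError("target_rr must lie strictly between 0 and 1")
    pop = _eligible(np.asarray(distances, dtype=float), kind)
    if pop.max() == pop.min():
        raise ValueError("all distances equal; recurrence rate is not controllable")
    return float(np.quantile(pop, target_rr))


def _realized(matrix: np.ndarray, kind: str) -> float:
    if kind == "auto":
        n = matrix.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(matrix[iu].mean())
    return float(matrix.mean())


def auto_recurrence(
    traj,
    epsilon: float | None = None,
    target_rr: float | None = None,
    norm: str = "euclidean",
) -> RecurrencePlot:
    """Auto-recurrence plot R_ij = Theta(eps - ||y_i - y_j||).

    Exactly one of ``epsilon`` and ``target_rr`` must be given. The line of
    identity stays in the matrix (it is removed when the plot becomes a
    network adjacency) but is excluded from the recurrence-rate accounting.
    """
    d = distance_matrix(traj, norm=norm)
    eps = _resolve_eps(d, epsilon, target_rr, "auto")
    m = (d < eps).astype(np.uint8)
    return RecurrencePlot(m, "auto", eps, _realized(m, "auto"), norm)


def cross_recurrence(
    traj_x,
    traj_y,
    epsilon: float | None = None,
    target_rr: float | None = None,
    norm: str = "euclidean",
) -> RecurrencePlot:
    """Cross-recurrence plot CR_ij = Theta(eps - ||x_i - y_j||), not symmetrized."""
    d = distance_matrix(traj_x, traj_y, norm=norm)
    eps = _resolve_eps(d, epsilon, target_rr, "cross")
    m = (d < eps).astype(np.uint8)
    return RecurrencePlot(m, "cross", eps, _realized(m, "cross"), norm)


def _resolve_eps(d, epsilon, target_rr, kind) -> float:
    if (epsilon is None) == (target_rr is None):
        raise ValueError("give exactly one of epsilon and target_rr")
    if epsilon is not None:
        return float(epsilon)
    return threshold_for_rr(d, target_rr, kind)
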