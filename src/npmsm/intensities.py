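"""Time grid, intensity jumps and product-integral probabilities.

The NPMLE of the cumulative transition intensities is a right-continuous
step function with jumps only at the sorted unique observation times
tau_1 < ... < tau_K.  The jump of A_gh at tau_k, written alpha[g, h, k], is
the conditional probability of a g -> h transition in the bin
(tau_{k-1}, tau_k].  Transition probability matrices follow by product
integration (Chapman-Kolmogorov):

    P(s, t) = prod_{k : s < tau_k <= t} (I + dA(tau_k))

where I + dA(tau_k) has off-diagonal entries alpha[g, h, k] and diagonal
1 - sum_h alpha[g, h, k].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConstraintError, ShapeError
from .graph import TransitionGraph

__all__ = [
    "TimeGrid",
    "IntensityGrid",
    "bin_generator_matrix",
    "product_integral",
    "cumulative_intensity",
]

#: row-stochasticity / constraint tolerance
ROW_TOL = 1e-10


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times tau_1 < ... < tau_K with an
    origin tau_0 (no mass is ever placed at tau_0).  Bin k is the half-open
    interval (tau_{k-1}, tau_k]."""

    tau: np.ndarray
    origin: float = 0.0

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        if tau.ndim != 1 or tau.size < 1:
            raise ShapeError("grid must contain at least one time")
        if np.any(np.diff(tau) <= 0):
            raise ShapeError("grid times must be strictly increasing")
        if tau[0] <= self.origin:
            raise ShapeError("all grid times must exceed the origin tau_0")

    @property
    def K(self) -> int:
        return self.tau.size

    def bin_range(self, s: float, t: float) -> tuple:
        """Half-open index range [lo, hi) of bins k with s < tau_k <= t
        (0-based into ``tau``)."""
        lo = int(np.searchsorted(self.tau, s, side="right"))
        hi = int(np.searchsorted(self.tau, t, side="right"))
        return lo, hi

    def index_of(self, t: float) -> int:
        """0-based index of t in the grid; raises if t is not a grid time."""
        k = int(np.searchsorted(self.tau, t))
        if k >= self.K or self.tau[k] != t:
            raise ShapeError(f"time {t} is not a grid point")
        return k


class IntensityGrid:
    """Jumps of the cumulative transition intensities on a time grid.

    Parameters
    ----------
    graph : TransitionGraph
    grid : TimeGrid
    alpha : ndarray, shape (K, H, H)
        ``alpha[k, g, h]`` is the jump of A_gh at tau_{k+1 in 1-based terms};
        entries off the allowed transition set must be zero.  Each (g, k)
        row mass ``sum_h alpha[k, g, :]`` must not exceed 1 (region C_alpha).
    """

    def __init__(self, graph: TransitionGraph, grid: TimeGrid, alpha: np.ndarray,
                 validate: bool = True):
        alpha = np.asarray(alpha, dtype=float)
        H = graph.n_states
        if alpha.shape != (grid.K, H, H):
            raise ShapeError(
                f"alpha must have shape (K={grid.K}, H={H}, H={H}), "
                f"got {alpha.shape}"
            )
        self.graph = graph
        self.grid = grid
        self.alpha = alpha
        if validate:
            self.validate()

    # -- constructors ------------------------------------------------------
    @classmethod
    def uniform(cls, graph: TransitionGraph, grid: TimeGrid) -> "IntensityGrid":
        """Uniform initial estimate alpha_ghk = 1/K on every allowed
        transition (the default EM starting point).

        On very coarse grids (K not much larger than a state's number of
        exits) 1/K per exit would push the total exit mass to 1, giving the
        staying path probability zero before the first iteration; the init
        is then scaled down to keep every row strictly inside C_alpha.
        """
        alpha = np.zeros((grid.K, graph.n_states, graph.n_states))
        for g, h in graph.transitions:
            n_exit = len(graph.successors(g))
            alpha[:, g, h] = min(1.0 / grid.K, 0.9 / n_exit)
        return cls(graph, grid, alpha)

    @classmethod
    def zeros(cls, graph: TransitionGraph, grid: TimeGrid) -> "IntensityGrid":
        H = graph.n_states
        return cls(graph, grid, np.zeros((grid.K, H, H)), validate=False)

    # -- validation --------------------------------------------------------
    def validate(self):
        mask = self.graph.transition_mask
        off = self.alpha[:, ~mask]
        if off.size and np.any(off != 0):
            raise ConstraintError("alpha has mass on a disallowed transition")
        if np.any(self.alpha < -ROW_TOL):
            raise ConstraintError("alpha has a negative jump")
        row = self.alpha.sum(axis=2)  # (K, H)
        if np.any(row > 1.0 + ROW_TOL):
            k, g = np.unravel_index(np.argmax(row), row.shape)
            raise ConstraintError(
                f"exit mass {row[k, g]:.6g} from state "
                f"{self.graph.label(g)!r} in bin {k + 1} exceeds 1"
            )

    # -- probability machinery --------------------------------------------
    def bin_matrices(self) -> np.ndarray:
        """All K one-bin transition matrices I + dA(tau_k), shape (K, H, H)."""
        K, H = self.grid.K, self.graph.n_states
        M = self.alpha.copy()
        diag = 1.0 - M.sum(axis=2)
        M[:, np.arange(H), np.arange(H)] = diag
        return M

    def bin_matrix(self, k: int) -> np.ndarray:
        """One-bin matrix for bin k (1-based, matching tau_k)."""
        if not 1 <= k <= self.grid.K:
            raise ShapeError(f"bin index {k} outside 1..{self.grid.K}")
        return self.bin_matrices()[k - 1]

    def product_integral(self, s: float, t: float) -> np.ndarray:
        """Transition probability matrix P(s, t), s <= t.

        s and t need not be grid points; the product runs over bins with
        s < tau_k <= t.  P(s, s) is the identity.
        """
        if t < s:
            raise ShapeError("product integral requires s <= t")
        H = self.graph.n_states
        lo, hi = self.grid.bin_range(s, t)
        P = np.eye(H)
        M = self.bin_matrices()
        for k in range(lo, hi):
            P = P @ M[k]
        return P

    def cumulative(self, from_state, to_state, t) -> np.ndarray | float:
        """Estimated cumulative intensity A_gh(t) = sum_{tau_k <= t} alpha_ghk
        (right-continuous step function; labels, scalar or array t)."""
        g = self.graph.index(from_state)
        h = self.graph.index(to_state)
        self.graph.transition_index(g, h)
        csum = np.concatenate([[0.0], np.cumsum(self.alpha[:, g, h])])
        idx = np.searchsorted(self.grid.tau, np.asarray(t, dtype=float),
                              side="right")
        out = csum[idx]
        return float(out) if np.isscalar(t) else out

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: transition_from, transition_to, tau, jump, cumulative."""
        rows = []
        for g, h in self.graph.transitions:
            jumps = self.alpha[:, g, h]
            rows.append(pd.DataFrame({
                "transition_from": self.graph.label(g),
                "transition_to": self.graph.label(h),
                "tau": self.grid.tau,
                "jump": jumps,
                "cumulative": np.cumsum(jumps),
            }))
        return pd.concat(rows, ignore_index=True)


# -- functional aliases matching the operation names ------------------------

def bin_generator_matrix(alpha: IntensityGrid, k: int) -> np.ndarray:
    """I + dA(tau_k) for bin k (1-based)."""
    M = alpha.bin_matrix(k)
    if np.any(M[np.arange(M.shape[0]), np.arange(M.shape[0])] < -ROW_TOL):
        raise ConstraintError(f"row mass exceeds 1 in bin {k}")
    return M


def product_integral(alpha: IntensityGrid, grid: TimeGrid, s: float, t: float
                     ) -> np.ndarray:
    if grid is not alpha.grid and not np.array_equal(grid.tau, alpha.grid.tau):
        raise ShapeError("grid does not match the intensity grid")
    return alpha.product_integral(s, t)


def cumulative_intensity(alpha: IntensityGrid, grid: TimeGrid,
                         transition: tuple, t):
    if grid is not alpha.grid and not np.array_equal(grid.tau, alpha.grid.tau):
        raise ShapeError("grid does not match the intensity grid")
    g, h = transition
    return alpha.cumulative(g, h, t)
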