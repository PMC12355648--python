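"""EM estimation of intensity jumps from interval-censored panels.

The complete-data log-likelihood (with jumps restricted to the unique
observation times) is, up to terms not involving alpha,

    l_C = sum_k sum_(g,h) d_ghk log(alpha_ghk) - alpha_ghk Y_gk

with d_ghk the number of g->h transitions in bin k and Y_gk the number of
subjects in g just before tau_k.  The E-step replaces d and Y by their
conditional expectations given the observed panel; the M-step maximizes over
the constraint region C_alpha = {alpha >= 0, sum_h alpha_ghk <= 1}:

    alpha_ghk = d_ghk / Y_gk              if mu_gk = 0
              = d_ghk / sum_h d_ghk       if mu_gk > 0

with Lagrange multiplier mu_gk = max(0, sum_h d_ghk - Y_gk).

For a subject interval ending in an exactly-observed entry (state b in E at
time tau_kr), the E-step conditions additionally on the entry occurring at
exactly tau_kr from some direct predecessor m of b occupied at tau_{kr-1}.

A Karush-Kuhn-Tucker stationarity residual (the reduced gradient of the
expected complete-data log-likelihood over C_alpha) provides a convergence
certificate that does not depend on the previous iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MaxIterWarning, ShapeError, ZeroPathError
from .graph import TransitionGraph
from .intensities import IntensityGrid
from .panel import PanelDataset

__all__ = [
    "ExpectedCounts",
    "FitConfig",
    "FitResult",
    "e_step",
    "e_step_exact",
    "expected_counts",
    "m_step",
    "observed_loglik",
    "reduced_gradient",
    "kkt_check",
    "fit_em",
]

_UNDERFLOW = 1e-300

try:  # optional JIT acceleration
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=True)
def _estep_kernel(M, alpha, tg, th, a_arr, b_arr, klo, khi, exact,
                  compute_counts):
    """Accumulate expected counts and the observed log-likelihood.

    M : (K, H, H) one-bin matrices for the current alpha
    alpha : (K, H, H) current jumps
    tg, th : transition index arrays (from/to states)
    a_arr, b_arr, klo, khi, exact : observation-interval columns
    Returns (d, Y, loglik, fail) with fail = index of the first interval
    whose probability underflowed to zero, or -1.

    Per interval the backward vectors over its bins are accumulated from the
    right and the forward vector from the left, so the cost is O(bins * H^2)
    rather than a fresh matrix product per bin.
    """
    K, H, _ = M.shape
    nt = tg.size
    d = np.zeros((K, H, H))
    Y = np.zeros((K, H))
    loglik = 0.0
    G = np.empty((K + 1, H))
    f = np.empty(H)
    fn = np.empty(H)

    for r in range(a_arr.size):
        k0 = klo[r]
        k1 = khi[r]
        a = a_arr[r]
        b = b_arr[r]
        nb = k1 - k0 + 1

        if exact[r]:
            # entry into b observed exactly at tau_{k1}; condition on the
            # direct predecessor occupied at tau_{k1 - 1}
            if nb >= 2:
                for h in range(H):
                    G[nb - 2, h] = alpha[k1, h, b]
                for j in range(nb - 2, 0, -1):
                    k = k0 + j
                    for g in range(H):
                        s = 0.0
                        for h in range(H):
                            s += M[k, g, h] * G[j, h]
                        G[j - 1, g] = s
                D = 0.0
                for h in range(H):
                    D += M[k0, a, h] * G[0, h]
            else:
                D = alpha[k1, a, b]
            if D <= _UNDERFLOW:
                return d, Y, loglik, r
            loglik += np.log(D)
            if compute_counts:
                for g in range(H):
                    f[g] = 0.0
                f[a] = 1.0
                for j in range(nb - 1):
                    k = k0 + j
                    for t in range(nt):
                        g = tg[t]
                        h = th[t]
                        if f[g] > 0.0 and alpha[k, g, h] > 0.0:
                            d[k, g, h] += f[g] * alpha[k, g, h] * G[j, h] / D
                    for g in range(H):
                        if f[g] > 0.0:
                            mg = 0.0
                            for h in range(H):
                                mg += M[k, g, h] * G[j, h]
                            Y[k, g] += f[g] * mg / D
                    for h in range(H):
                        s = 0.0
                        for g in range(H):
                            s += f[g] * M[k, g, h]
                        fn[h] = s
                    for h in range(H):
                        f[h] = fn[h]
                # terminal bin: the m -> b jump happens at tau_{k1}; the
                # subject is at risk in the predecessor it occupies there
                for m in range(H):
                    w = alpha[k1, m, b]
                    if w > 0.0 and f[m] > 0.0:
                        val = f[m] * w / D
                        d[k1, m, b] += val
                        Y[k1, m] += val
        else:
            for h in range(H):
                G[nb - 1, h] = 0.0
            G[nb - 1, b] = 1.0
            for j in range(nb - 1, 0, -1):
                k = k0 + j
                for g in range(H):
                    s = 0.0
                    for h in range(H):
                        s += M[k, g, h] * G[j, h]
                    G[j - 1, g] = s
            den = 0.0
            for h in range(H):
                den += M[k0, a, h] * G[0, h]
            if den <= _UNDERFLOW:
                return d, Y, loglik, r
            loglik += np.log(den)
            if compute_counts:
                for g in range(H):
                    f[g] = 0.0
                f[a] = 1.0
                for j in range(nb):
                    k = k0 + j
                    for t in range(nt):
                        g = tg[t]
                        h = th[t]
                        if f[g] > 0.0 and alpha[k, g, h] > 0.0:
                            d[k, g, h] += f[g] * alpha[k, g, h] * G[j, h] / den
                    for g in range(H):
                        if f[g] > 0.0:
                            mg = 0.0
                            for h in range(H):
                                mg += M[k, g, h] * G[j, h]
                            Y[k, g] += f[g] * mg / den
                    for h in range(H):
                        s = 0.0
                        for g in range(H):
                            s += f[g] * M[k, g, h]
                        fn[h] = s
                    for h in range(H):
                        f[h] = fn[h]
    return d, Y, loglik, -1


@dataclass
class ExpectedCounts:
    """E-step output: expected transition counts and at-risk totals.

    d[k, g, h] is the expected number of g->h jumps in bin k summed over
    subjects; Y[k, g] the expected number of subjects in g just before
    tau_k.  ``loglik`` is the observed-data log-likelihood of the intensity
    vector the counts were computed at (over the intervals included).
    """

    d: np.ndarray
    Y: np.ndarray
    loglik: float

    def __add__(self, other: "ExpectedCounts") -> "ExpectedCounts":
        return ExpectedCounts(self.d + other.d, self.Y + other.Y,
                              self.loglik + other.loglik)


def _run_kernel(alpha: IntensityGrid, dataset: PanelDataset, select,
                compute_counts: bool):
    iv = dataset.intervals
    mask = np.ones(iv.n, dtype=bool) if select is None else select
    tg = np.array([g for g, _ in alpha.graph.transitions], dtype=np.int64)
    th = np.array([h for _, h in alpha.graph.transitions], dtype=np.int64)
    return _estep_kernel(
        alpha.bin_matrices(), alpha.alpha, tg, th,
        iv.a[mask], iv.b[mask], iv.klo[mask], iv.khi[mask], iv.exact[mask],
        compute_counts,
    ), np.nonzero(mask)[0]


def _counts(alpha: IntensityGrid, dataset: PanelDataset, select
            ) -> ExpectedCounts:
    (d, Y, ll, fail), rows = _run_kernel(alpha, dataset, select, True)
    if fail >= 0:
        iv = dataset.intervals
        r = rows[fail]
        sid = dataset.paths[iv.subj[r]].subject_id
        raise ZeroPathError(
            f"subject {sid!r}: observed pair "
            f"{dataset.graph.label(iv.a[r])!r} -> {dataset.graph.label(iv.b[r])!r} "
            f"over ({iv.t_prev[r]}, {iv.t_next[r]}] has zero probability "
            "under the current intensities"
        )
    return ExpectedCounts(d, Y, ll)


def e_step(alpha_tilde: IntensityGrid, dataset: PanelDataset
           ) -> ExpectedCounts:
    """Expected counts from the purely interval-censored frames."""
    return _counts(alpha_tilde, dataset, ~dataset.intervals.exact)


def e_step_exact(alpha_tilde: IntensityGrid, dataset: PanelDataset
                 ) -> ExpectedCounts:
    """Expected counts from frames ending in an exactly-observed entry."""
    return _counts(alpha_tilde, dataset, dataset.intervals.exact)


def expected_counts(alpha_tilde: IntensityGrid, dataset: PanelDataset
                    ) -> ExpectedCounts:
    """Full E-step over all frames (interval-censored and exact)."""
    return _counts(alpha_tilde, dataset, None)


def observed_loglik(alpha: IntensityGrid, dataset: PanelDataset) -> float:
    """Observed-data log-likelihood of ``alpha``.

    Each consecutive visit pair contributes log P_{a,b}(l, r); a pair ending
    in an exactly-observed entry into b at tau_k contributes
    log sum_{m in R_b} P_{a,m}(l, tau_{k-1}) alpha_{m b, k}.  Returns -inf
    if any factor is zero.
    """
    (_d, _Y, ll, fail), _rows = _run_kernel(alpha, dataset, None, False)
    if fail >= 0:
        return -np.inf
    return ll


def m_step(counts: ExpectedCounts, graph: TransitionGraph,
           grid) -> IntensityGrid:
    """Constrained maximizer of the expected complete-data log-likelihood.

    Where the unconstrained update d/Y would push the total exit mass of a
    state above 1, the multiplier mu_gk > 0 is active and the exits are
    renormalized to sum to exactly 1.  Empty risk sets (Y = 0, hence d = 0)
    yield a zero jump.
    """
    d, Y = counts.d, counts.Y
    sum_d = d.sum(axis=2)
    mu = np.maximum(0.0, sum_d - Y)
    denom = np.where(mu > 0.0, sum_d, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(denom[:, :, None] > 0.0, d / denom[:, :, None], 0.0)
    return IntensityGrid(graph, grid, alpha)


def reduced_gradient(alpha: IntensityGrid, counts: ExpectedCounts
                     ) -> np.ndarray:
    """KKT stationarity residual of the expected complete-data likelihood.

    For alpha_ghk > 0 the residual is d_ghk/alpha_ghk - Y_gk - mu_gk; it
    vanishes exactly at an M-step fixed point.  For alpha_ghk = 0 only a
    one-sided improvement direction matters: since d_ghk = 0 whenever
    alpha_ghk = 0 (zero jumps are absorbing under EM), these coordinates
    never block convergence; a guard keeps them from dividing by zero.
    """
    d, Y = counts.d, counts.Y
    mu = np.maximum(0.0, d.sum(axis=2) - Y)
    lam = (Y + mu)[:, :, None]
    grad = np.zeros_like(d)
    mask = alpha.graph.transition_mask[None, :, :] & (alpha.alpha > 0.0)
    grad[mask] = d[mask] / alpha.alpha[mask] - np.broadcast_to(lam, d.shape)[mask]
    zero = alpha.graph.transition_mask[None, :, :] & (alpha.alpha == 0.0)
    grad[zero] = np.maximum(
        0.0, d[zero] / 1e-12 - np.broadcast_to(lam, d.shape)[zero]
    )
    return grad


def kkt_check(alpha: IntensityGrid, counts: ExpectedCounts,
              kkt_eps: float = 1e-4) -> bool:
    """True iff the maximal reduced gradient is below ``kkt_eps``."""
    return float(reduced_gradient(alpha, counts).max()) < kkt_eps


@dataclass
class FitConfig:
    """EM settings.

    tol : stopping tolerance (largest intensity change, or absolute
        log-likelihood change, depending on ``criterion``)
    criterion : one of 'intensity', 'likelihood', 'kkt'
    max_iter : iteration cap (a MaxIterWarning is issued if reached)
    init : optional user-supplied IntensityGrid; must be strictly positive
        on every allowed transition/bin since zero jumps are absorbing
    kkt_eps : threshold for the KKT certificate
    """

    tol: float = 1e-4
    criterion: str = "intensity"
    max_iter: int = 5000
    init: IntensityGrid | None = None
    kkt_eps: float = 1e-4

    def __post_init__(self):
        if self.tol <= 0:
            raise ShapeError("tol must be positive")
        if self.criterion not in ("intensity", "likelihood", "kkt"):
            raise ShapeError(f"unknown criterion {self.criterion!r}")


@dataclass
class FitResult:
    """Converged intensities plus the full iteration trace."""

    alpha_hat: IntensityGrid
    n_iter: int
    loglik: float
    stop_reason: str
    converged: bool
    trace_loglik: np.ndarray = field(repr=False)
    trace_max_delta: np.ndarray = field(repr=False)
    trace_max_grad: np.ndarray = field(repr=False)
    final_counts: ExpectedCounts = field(repr=False, default=None)
    max_reduced_gradient: float = np.nan

    @property
    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iter + 1),
            "loglik": self.trace_loglik,
            "max_delta": self.trace_max_delta,
            "max_reduced_gradient": self.trace_max_grad,
        })


def fit_em(dataset: PanelDataset, config: FitConfig | None = None,
           verbose: bool = False) -> FitResult:
    """Run the EM algorithm until the configured stopping rule fires."""
    config = config or FitConfig()
    graph, grid = dataset.graph, dataset.grid
    if config.init is not None:
        alpha = config.init
        mask = graph.transition_mask
        if np.any(alpha.alpha[:, mask] <= 0.0):
            warnings.warn(
                "initial intensities contain zeros on allowed transitions; "
                "those jumps can never become positive",
                UserWarning,
                stacklevel=2,
            )
    else:
        alpha = IntensityGrid.uniform(graph, grid)

    tmask = graph.transition_mask  # (H, H), applied to the trailing axes
    lls, deltas, grads = [], [], []
    stop_reason, converged = "max_iter", False
    prev_ll = None
    n_iter = 0

    for it in range(1, config.max_iter + 1):
        n_iter = it
        counts = expected_counts(alpha, dataset)
        maxgrad = float(reduced_gradient(alpha, counts)[:, tmask].max(initial=0.0))
        new = m_step(counts, graph, grid)
        delta = float(np.abs(new.alpha - alpha.alpha)[:, tmask].max(initial=0.0))
        lls.append(counts.loglik)
        deltas.append(delta)
        grads.append(maxgrad)
        if verbose:
            print(f"iter {it:5d}  loglik {counts.loglik:.8f}  "
                  f"max|dalpha| {delta:.3e}  max grad {maxgrad:.3e}")

        if config.criterion == "kkt" and maxgrad < config.kkt_eps:
            stop_reason, converged = "kkt", True
            break
        if config.criterion == "intensity" and delta < config.tol:
            alpha = new
            stop_reason, converged = "intensity", True
            break
        if (config.criterion == "likelihood" and prev_ll is not None
                and abs(counts.loglik - prev_ll) < config.tol):
            stop_reason, converged = "likelihood", True
            break
        prev_ll = counts.loglik
        alpha = new

    if not converged:
        warnings.warn(
            f"EM did not converge within {config.max_iter} iterations "
            f"(criterion {config.criterion!r}, tol {config.tol})",
            MaxIterWarning,
            stacklevel=2,
        )

    final_counts = expected_counts(alpha, dataset)
    final_grad = float(reduced_gradient(alpha, final_counts)[:, tmask].max(initial=0.0))
    return FitResult(
        alpha_hat=alpha,
        n_iter=n_iter,
        loglik=final_counts.loglik,
        stop_reason=stop_reason,
        converged=converged,
        trace_loglik=np.array(lls),
        trace_max_delta=np.array(deltas),
        trace_max_grad=np.array(grads),
        final_counts=final_counts,
        max_reduced_gradient=final_grad,
    )
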