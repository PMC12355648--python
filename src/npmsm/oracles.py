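"""Independent reference implementations used for testing only.

Two cross-checks for the EM estimator:

* :func:`turnbull_fit` -- the classical self-consistency NPMLE for a
  two-state (survival) reduction, computed on Turnbull's innermost
  intervals.  Agreement is asserted on the log-likelihood, not on the jump
  locations, because the NPMLE only identifies the total mass per support
  interval.
* :func:`brute_force_mle` -- direct multi-start constrained maximization of
  the observed-data log-likelihood on tiny instances, with its own naive
  likelihood evaluator (plain ordered matrix products, no shared code with
  the EM path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .exceptions import DimensionError
from .panel import PanelDataset

__all__ = ["TurnbullResult", "turnbull_fit", "two_state_intervals",
           "naive_loglik", "brute_force_mle"]


def two_state_intervals(dataset: PanelDataset) -> list:
    """Censoring intervals (L, R] for a two-state (survival) panel.

    L is the last visit in the initial state; R the first visit in the
    event state, or inf if the subject never left (right-censored at the
    last visit)."""
    if dataset.graph.n_states != 2:
        raise DimensionError("survival reduction needs exactly two states")
    out = []
    for p in dataset.paths:
        if p.states[-1] == 0:
            out.append((float(p.times[-1]), np.inf))
        else:
            j = int(np.nonzero(p.states == 0)[0][-1])
            out.append((float(p.times[j]), float(p.times[j + 1])))
    return out


@dataclass
class TurnbullResult:
    """Masses on the innermost intervals (l_j, r_j]; r_j = inf collects the
    never-event mass of right-censored subjects."""

    intervals: list
    masses: np.ndarray
    loglik: float
    n_iter: int

    def cdf(self, times) -> np.ndarray:
        """Distribution function placing each mass at its interval's right
        endpoint (right-continuous step function)."""
        rights = np.array([r for (_, r) in self.intervals])
        times = np.asarray(times, dtype=float)
        out = np.empty(times.shape)
        for i, t in np.ndenumerate(times):
            out[i] = self.masses[rights <= t].sum()
        return out


def _innermost_intervals(lefts, rights):
    """Turnbull's innermost intervals for censoring intervals (L, R].

    An innermost interval (l, r] has l in {L_i}, r in {R_i}, l < r, and no
    other endpoint strictly inside.  At tied values a right endpoint
    (closed) precedes a left endpoint (open), so no empty interval forms.
    """
    events = sorted(
        [(v, 1) for v in set(lefts)] + [(v, 0) for v in set(rights)]
    )  # type 0 = right endpoint first on ties
    out = []
    for i in range(len(events) - 1):
        v, typ = events[i]
        nv, ntyp = events[i + 1]
        if typ == 1 and ntyp == 0:
            out.append((v, nv))
    return out


def turnbull_fit(intervals, tol: float = 1e-10, max_iter: int = 100000
                 ) -> TurnbullResult:
    """Self-consistency NPMLE for interval-censored event times.

    intervals : iterable of (L, R) pairs meaning the event lies in (L, R];
        R = inf encodes right censoring at L.
    """
    lefts = np.array([l for l, _ in intervals], dtype=float)
    rights = np.array([r for _, r in intervals], dtype=float)
    inner = _innermost_intervals(lefts, rights)
    J = len(inner)
    # membership: innermost_j subset of (L_i, R_i]
    A = np.zeros((lefts.size, J), dtype=bool)
    for j, (l, r) in enumerate(inner):
        A[:, j] = (lefts <= l) & (r <= rights)
    if np.any(~A.any(axis=1)):  # pragma: no cover - cannot happen by constr.
        raise ValueError("subject interval covers no innermost interval")
    s = np.full(J, 1.0 / J)
    n = lefts.size
    it = 0
    for it in range(1, max_iter + 1):
        denom = A @ s
        new = s * (A / denom[:, None]).sum(axis=0) / n
        if np.max(np.abs(new - s)) < tol:
            s = new
            break
        s = new
    loglik = float(np.log(A @ s).sum())
    return TurnbullResult(inner, s, loglik, it)


def naive_loglik(alpha: np.ndarray, dataset: PanelDataset) -> float:
    """Observed-data log-likelihood by plain ordered matrix products.

    Independent of the EM module's accumulation scheme; used as the
    objective of the brute-force oracle and as a dual-route consistency
    check.  ``alpha`` has shape (K, H, H).
    """
    g = dataset.graph
    H = g.n_states
    M = alpha.copy()
    M[:, np.arange(H), np.arange(H)] = 1.0 - alpha.sum(axis=2)

    def pmat(lo, hi):
        P = np.eye(H)
        for k in range(lo, hi + 1):
            P = P @ M[k]
        return P

    ll = 0.0
    iv = dataset.intervals
    for r in range(iv.n):
        a, b, k0, k1 = iv.a[r], iv.b[r], iv.klo[r], iv.khi[r]
        if iv.exact[r]:
            term = 0.0
            P = pmat(k0, k1 - 1) if k1 > k0 else np.eye(H)
            for m in g.reachable_from(b):
                term += P[a, m] * alpha[k1, m, b]
        else:
            term = pmat(k0, k1)[a, b]
        if term <= 0.0:
            return -np.inf
        ll += np.log(term)
    return float(ll)


def brute_force_mle(dataset: PanelDataset, n_starts: int = 20, seed: int = 0,
                    tol: float = 1e-9):
    """Multi-start constrained maximizer of the observed log-likelihood.

    Capped at H <= 3 states, K <= 3 bins and n <= 4 subjects
    (:class:`DimensionError` otherwise).  Returns (alpha, loglik) with alpha
    of shape (K, H, H).
    """
    g = dataset.graph
    K, H = dataset.grid.K, g.n_states
    if H > 3 or K > 3 or dataset.n_subjects > 4:
        raise DimensionError(
            f"instance too large for brute force (H={H}, K={K}, "
            f"n={dataset.n_subjects})"
        )
    trans = list(g.transitions)
    npar = len(trans) * K

    def unpack(x):
        alpha = np.zeros((K, H, H))
        for j, (gg, hh) in enumerate(trans):
            alpha[:, gg, hh] = x[j * K:(j + 1) * K]
        return alpha

    def neg_ll(x):
        return -naive_loglik(unpack(x), dataset)

    constraints = []
    for gg in {t[0] for t in trans}:
        for k in range(K):
            idx = tuple(j * K + k for j, t in enumerate(trans) if t[0] == gg)
            constraints.append({
                "type": "ineq",
                "fun": (lambda x, idx=idx: 1.0 - sum(x[i] for i in idx)),
            })
    bounds = [(0.0, 1.0)] * npar

    rng = np.random.default_rng(seed)
    best_x, best_ll = None, -np.inf
    starts = [np.full(npar, 1.0 / (2 * K))]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(0.01, 0.9 / K, size=npar))
    for x0 in starts:
        res = minimize(neg_ll, x0, method="SLSQP", bounds=bounds,
                       constraints=constraints,
                       options={"ftol": tol * 1e-3, "maxiter": 500})
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll, best_x = -res.fun, res.x
    return unpack(best_x), float(best_ll)
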