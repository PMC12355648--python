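"""Model/Results interface for the panel-data NPMLE.

Usage::

    model = PanelMarkovModel.from_dataframe(
        df, transitions=[(1, 2), (1, 3), (2, 3)], exact_states=[3])
    res = model.fit(tol=1e-4)
    res.summary()
    res.cumulative_intensity(1, 2, times=[2, 5, 10])
    res.transition_probability(0, 15)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .em import FitConfig, FitResult, fit_em, observed_loglik
from .graph import validate_graph
from .intensities import IntensityGrid
from .panel import PanelDataset

__all__ = ["PanelMarkovModel", "PanelMarkovResults"]


class PanelMarkovModel:
    """Nonparametric Markov multistate model for interval-censored panels.

    Parameters
    ----------
    dataset : PanelDataset
        Validated panel observations.
    """

    def __init__(self, dataset: PanelDataset):
        self.dataset = dataset
        self.graph = dataset.graph

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, transitions, states=None,
                       exact_states=()) -> "PanelMarkovModel":
        """Build model and transition structure from a long-format frame
        (columns subject_id, time, state).  ``states`` defaults to the
        sorted set of labels appearing in ``transitions``."""
        if states is None:
            seen = []
            for g, h in transitions:
                for s in (g, h):
                    if s not in seen:
                        seen.append(s)
            try:
                states = sorted(seen)
            except TypeError:
                states = seen
        graph = validate_graph(states, transitions, exact_states)
        return cls(PanelDataset.from_dataframe(df, graph))

    def fit(self, tol: float = 1e-4, criterion: str = "intensity",
            max_iter: int = 5000, init: IntensityGrid | None = None,
            kkt_eps: float = 1e-4, verbose: bool = False
            ) -> "PanelMarkovResults":
        """Run the EM algorithm and wrap the outcome in a results object."""
        config = FitConfig(tol=tol, criterion=criterion, max_iter=max_iter,
                           init=init, kkt_eps=kkt_eps)
        raw = fit_em(self.dataset, config, verbose=verbose)
        return PanelMarkovResults(self, raw, config)

    def loglike(self, alpha: IntensityGrid) -> float:
        """Observed-data log-likelihood at an arbitrary intensity grid."""
        return observed_loglik(alpha, self.dataset)


class PanelMarkovResults:
    """Estimated intensity jumps with diagnostics and derived quantities."""

    def __init__(self, model: PanelMarkovModel, raw: FitResult,
                 config: FitConfig):
        self.model = model
        self.config = config
        self._raw = raw
        self.alpha = raw.alpha_hat
        self.n_iter = raw.n_iter
        self.loglik = raw.loglik
        self.converged = raw.converged
        self.stop_reason = raw.stop_reason
        self.max_reduced_gradient = raw.max_reduced_gradient

    # -- derived quantities ------------------------------------------------
    @property
    def trace(self) -> pd.DataFrame:
        """Per-iteration log-likelihood, intensity change and KKT residual."""
        return self._raw.trace

    def cumulative_intensity(self, from_state, to_state, times=None):
        """A_gh evaluated at ``times`` (default: the grid itself)."""
        if times is None:
            times = self.alpha.grid.tau
        return self.alpha.cumulative(from_state, to_state, times)

    def intensity_frame(self) -> pd.DataFrame:
        """Tidy jumps/cumulative intensities, one row per transition/time."""
        return self.alpha.to_frame()

    def transition_probability(self, s: float, t: float) -> pd.DataFrame:
        """P(s, t) as a labelled H x H DataFrame."""
        P = self.alpha.product_integral(s, t)
        labels = list(self.model.graph.states)
        return pd.DataFrame(P, index=labels, columns=labels)

    def state_occupation(self, start_state, times) -> pd.DataFrame:
        """P(X(t) = h | X(origin) = start) for each state h over ``times``."""
        g = self.model.graph.index(start_state)
        origin = self.alpha.grid.origin
        rows = [self.alpha.product_integral(origin, t)[g] for t in times]
        return pd.DataFrame(rows, index=pd.Index(times, name="time"),
                            columns=list(self.model.graph.states))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        g = self.model.graph
        ds = self.model.dataset
        grid = self.alpha.grid
        lines = [
            "Panel Markov multistate model (NPMLE via EM)",
            "=" * 52,
            f"subjects: {ds.n_subjects}    observations: {ds.n_observations}",
            f"states: {list(g.states)}    "
            f"exact: {[g.label(e) for e in sorted(g.exact_states)]}",
            f"grid points: {grid.K}    origin tau_0 = {grid.origin:g}",
            f"iterations: {self.n_iter}    stop: {self.stop_reason}"
            f"    converged: {self.converged}",
            f"log-likelihood: {self.loglik:.6f}",
            f"max reduced gradient (KKT residual): "
            f"{self.max_reduced_gradient:.3e}",
            "-" * 52,
            f"{'transition':>14}  {'jumps>0':>8}  {'A(horizon)':>11}",
        ]
        for gi, hi in g.transitions:
            jumps = self.alpha.alpha[:, gi, hi]
            lines.append(
                f"{g.label(gi)!s:>6} -> {g.label(hi)!s:<4}  "
                f"{int((jumps > 1e-12).sum()):>8d}  "
                f"{jumps.sum():>11.4f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PanelMarkovResults n_iter={self.n_iter} "
                f"loglik={self.loglik:.4f} stop={self.stop_reason!r}>")
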