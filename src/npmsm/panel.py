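"""Interval-censored panel data: reading, validation and bin frames.

A panel records, for every subject i, the occupied state at each visit time
t_i0 < t_i1 < ... < t_in_i.  Transitions are only known to have happened
somewhere between two visits.  The estimator works on the grid of sorted
unique visit times tau_1 < ... < tau_K; for each subject and each grid bin
(tau_{k-1}, tau_k] the E-step needs the enclosing observation interval

    l_ik = last visit time <= tau_{k-1},    r_ik = first visit time >= tau_k

together with the states a_ik = X_i(l_ik) and b_ik = X_i(r_ik).  Bins
outside a subject's observation span are inactive and contribute nothing
(the last visit acts as the right-censoring time).

Internally the per-bin frames are stored compactly per *observation
interval* (one row per consecutive visit pair), since every bin inside the
same visit pair shares (l, r, a, b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError
from .graph import TransitionGraph
from .intensities import TimeGrid

__all__ = [
    "ObservationPath",
    "PanelDataset",
    "read_panel",
    "write_panel",
    "build_bin_frames",
]


@dataclass
class ObservationPath:
    """One subject's visit times and observed states (0-based indices)."""

    subject_id: object
    times: np.ndarray
    states: np.ndarray

    def __len__(self):
        return self.times.size


@dataclass
class _Intervals:
    """Observation intervals for all subjects, columnar.

    One row per consecutive visit pair (t_prev, t_next]; ``klo``/``khi`` are
    the 0-based inclusive indices of the grid bins contained in the pair.
    ``exact`` marks intervals that end with an exactly-observed entry
    (b in E, a != b); for those, t_next == tau_{khi+1 (1-based)} is the
    recorded entry time.
    """

    subj: np.ndarray
    a: np.ndarray
    b: np.ndarray
    t_prev: np.ndarray
    t_next: np.ndarray
    klo: np.ndarray
    khi: np.ndarray
    exact: np.ndarray

    @property
    def n(self) -> int:
        return self.subj.size


class PanelDataset:
    """Validated panel with its derived time grid and bin frames."""

    def __init__(self, paths: list, graph: TransitionGraph,
                 extra_times=None):
        """``extra_times`` forces additional grid points (useful to place
        potential jumps at times no subject was visited at, e.g. when
        comparing fits across datasets on a common grid)."""
        self.graph = graph
        self.paths = paths
        self._validate_paths()
        self.grid = self._build_grid(extra_times)
        self.intervals = self._build_intervals()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, graph: TransitionGraph
                       ) -> "PanelDataset":
        """Build from a long-format frame with columns subject_id, time,
        state.  Duplicate (subject, time) rows with equal states are
        deduplicated; conflicting states raise :class:`ConsistencyError`."""
        required = {"subject_id", "time", "state"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"missing columns: {sorted(missing)}")
        try:
            times = df["time"].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric time values: {exc}") from None
        if times.isna().any():
            raise FormatError("missing/NaN time values")

        label_map = {}
        for i, s in enumerate(graph.states):
            label_map[s] = i
            label_map[str(s)] = i

        paths = []
        work = df.assign(_t=times)
        for sid, grp in work.groupby("subject_id", sort=False):
            grp = grp.sort_values("_t", kind="stable")
            t, x = [], []
            for _, row in grp.iterrows():
                try:
                    st = label_map[row["state"]]
                except KeyError:
                    raise FormatError(
                        f"subject {sid!r}: unknown state {row['state']!r}"
                    ) from None
                if t and row["_t"] == t[-1]:
                    if st != x[-1]:
                        raise ConsistencyError(
                            f"subject {sid!r}: conflicting states at time "
                            f"{row['_t']}"
                        )
                    continue  # exact duplicate
                t.append(float(row["_t"]))
                x.append(st)
            paths.append(ObservationPath(sid, np.array(t), np.array(x, dtype=int)))
        return cls(paths, graph)

    # -- validation --------------------------------------------------------
    def _validate_paths(self):
        g = self.graph
        for p in self.paths:
            if np.any(np.diff(p.times) <= 0):
                raise ConsistencyError(
                    f"subject {p.subject_id!r}: non-increasing visit times"
                )
            for j in range(1, len(p)):
                a, b = p.states[j - 1], p.states[j]
                if not g.can_reach(a, b):
                    raise ConsistencyError(
                        f"subject {p.subject_id!r}: no directed path from "
                        f"state {g.label(a)!r} to {g.label(b)!r} "
                        f"(times {p.times[j-1]} -> {p.times[j]})"
                    )

    def _build_grid(self, extra_times=None) -> TimeGrid:
        # grid = sorted unique post-baseline visit times; origin = earliest
        # first visit.  Mass is never placed at the origin.
        later = [p.times[1:] for p in self.paths if len(p) > 1]
        if not later or not any(t.size for t in later):
            raise ConsistencyError(
                "no subject has more than one visit; nothing to estimate"
            )
        origin = min(float(p.times[0]) for p in self.paths)
        if extra_times is not None:
            later = later + [np.asarray(extra_times, dtype=float)]
        tau = np.unique(np.concatenate(later))
        tau = tau[tau > origin]
        return TimeGrid(tau, origin=origin)

    def _build_intervals(self) -> _Intervals:
        tau = self.grid.tau
        E = self.graph.exact_states
        subj, a_, b_, tp, tn, klo, khi, ex = [], [], [], [], [], [], [], []
        for i, p in enumerate(self.paths):
            for j in range(1, len(p)):
                t0, t1 = p.times[j - 1], p.times[j]
                a, b = int(p.states[j - 1]), int(p.states[j])
                lo = int(np.searchsorted(tau, t0, side="right"))
                hi = int(np.searchsorted(tau, t1, side="right")) - 1
                # t1 is a post-baseline visit time, hence a grid point
                assert hi >= lo and tau[hi] == t1
                subj.append(i)
                a_.append(a)
                b_.append(b)
                tp.append(t0)
                tn.append(t1)
                klo.append(lo)
                khi.append(hi)
                ex.append(b in E and a != b)
        return _Intervals(
            subj=np.array(subj, dtype=np.int64),
            a=np.array(a_, dtype=np.int64),
            b=np.array(b_, dtype=np.int64),
            t_prev=np.array(tp, dtype=float),
            t_next=np.array(tn, dtype=float),
            klo=np.array(klo, dtype=np.int64),
            khi=np.array(khi, dtype=np.int64),
            exact=np.array(ex, dtype=bool),
        )

    # -- views -------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.paths)

    @property
    def n_observations(self) -> int:
        return sum(len(p) for p in self.paths)

    def subject_ids(self) -> list:
        return [p.subject_id for p in self.paths]

    def to_frame(self) -> pd.DataFrame:
        g = self.graph
        rows = [
            {"subject_id": p.subject_id, "time": t, "state": g.label(s)}
            for p in self.paths
            for t, s in zip(p.times, p.states)
        ]
        return pd.DataFrame(rows, columns=["subject_id", "time", "state"])

    def bin_frames(self) -> pd.DataFrame:
        """Per-subject, per-bin frames (l, r, a, b) as a tidy table.

        One row per active (subject, bin) pair: ``k`` is the 1-based bin
        index, ``l``/``r`` the enclosing visit times, ``a``/``b`` the state
        labels at those visits.  ``exact_terminal`` marks frames whose right
        state is an exactly-observed entry; ``k_r`` is then the 1-based bin
        index of the entry time.
        """
        g, tau = self.graph, self.grid.tau
        iv = self.intervals
        recs = []
        for r in range(iv.n):
            for k in range(iv.klo[r], iv.khi[r] + 1):
                recs.append({
                    "subject_id": self.paths[iv.subj[r]].subject_id,
                    "k": k + 1,
                    "tau": tau[k],
                    "l": iv.t_prev[r],
                    "r": iv.t_next[r],
                    "a": g.label(iv.a[r]),
                    "b": g.label(iv.b[r]),
                    "exact_terminal": bool(iv.exact[r]),
                    "k_r": iv.khi[r] + 1 if iv.exact[r] else pd.NA,
                })
        return pd.DataFrame(recs)


def read_panel(path, graph: TransitionGraph, fmt: str | None = None
               ) -> PanelDataset:
    """Read a long-format CSV/TSV panel (columns subject_id, time, state)."""
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    return PanelDataset.from_dataframe(df, graph)


def write_panel(dataset: PanelDataset, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = "\t" if fmt == "tsv" else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def build_bin_frames(dataset: PanelDataset) -> pd.DataFrame:
    """Operation-style alias for :meth:`PanelDataset.bin_frames`."""
    return dataset.bin_frames()
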