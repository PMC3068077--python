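"""Data model and file I/O for categorical adherence state sequences.

A cohort is a set of subjects, each observed at the same ``T`` visits; at
every visit the subject is in one of ``S`` categorical adherence states.
A missed or incomplete visit is itself a state (conventionally coded ``9``),
so sequences are always complete and of equal length.

Wide layout: one row per subject, ``subject,v1,...,vT``.
Long layout: one row per (subject, visit), ``subject,visit,state`` with
1-based contiguous visit indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "Trajectory",
    "Cohort",
    "read_cohort",
    "read_outcomes",
    "write_assignments",
    "read_assignments",
    "profile_count",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered alphabet of adherence states, one of which may mean "missing".

    Parameters
    ----------
    labels
        Distinct state codes, e.g. ``("0", "1", "9")``. Order fixes the
        index of every state in vectors and matrices downstream.
    missing_label
        The code representing a missed/incomplete visit, or ``None`` if the
        data have no missingness state. Must be one of ``labels``.
    """

    labels: tuple[str, ...]
    missing_label: str | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a state space needs at least 2 states")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate state labels: {labels}")
        if self.missing_label is not None:
            object.__setattr__(self, "missing_label", str(self.missing_label))
            if self.missing_label not in labels:
                raise ValueError(
                    f"missing_label {self.missing_label!r} not in labels {labels}"
                )

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown state code {label!r}; known: {self.labels}")

    def encode(self, states: Sequence[str]) -> np.ndarray:
        """Map a label sequence to integer codes 0..S-1."""
        return np.array([self.index(s) for s in states], dtype=np.intp)

    def decode(self, codes: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.labels[c] for c in codes)


def default_state_space() -> StateSpace:
    """The 3-state coding: 0 = missed a dose, 1 = no dose missed, 9 = missing."""
    return StateSpace(labels=("0", "1", "9"), missing_label="9")


@dataclass(frozen=True)
class Trajectory:
    """One subject's ordered state sequence X_1..X_T."""

    subject_id: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise ValueError(
                f"trajectory {self.subject_id!r} has length {len(self.states)}; "
                "need at least 2 visits (one transition)"
            )

    def __len__(self) -> int:
        return len(self.states)


class Cohort:
    """Equal-length trajectories over one state space, with optional outcomes.

    Internally states are held as an (N, T) integer code array for fast
    counting; the :class:`Trajectory` view is reconstructed on demand.
    """

    def __init__(
        self,
        state_space: StateSpace,
        trajectories: Sequence[Trajectory],
        outcomes: Sequence[int] | None = None,
        covariates: pd.DataFrame | None = None,
    ):
        self.state_space = state_space
        trajs = list(trajectories)
        if not trajs:
            self._codes = np.empty((0, 0), dtype=np.intp)
            self.subject_ids: tuple[str, ...] = ()
        else:
            T = len(trajs[0])
            for tr in trajs:
                if len(tr) != T:
                    raise ValueError(
                        f"trajectory {tr.subject_id!r} has length {len(tr)}; "
                        f"cohort length is {T}"
                    )
            ids = [tr.subject_id for tr in trajs]
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate subject ids: {dupes}")
            self.subject_ids = tuple(ids)
            self._codes = np.vstack([state_space.encode(tr.states) for tr in trajs])
        self.outcomes = None if outcomes is None else np.asarray(outcomes, dtype=int)
        if self.outcomes is not None:
            if len(self.outcomes) != self.n_subjects:
                raise ValueError(
                    f"{len(self.outcomes)} outcomes for {self.n_subjects} subjects"
                )
            if not np.isin(self.outcomes, (0, 1)).all():
                raise ValueError("outcomes must be binary 0/1")
        self.covariates = covariates
        if covariates is not None and len(covariates) != self.n_subjects:
            raise ValueError("covariates do not align with trajectories")

    @classmethod
    def from_codes(
        cls,
        state_space: StateSpace,
        codes: np.ndarray,
        subject_ids: Sequence[str] | None = None,
        outcomes: Sequence[int] | None = None,
    ) -> "Cohort":
        """Build directly from an (N, T) integer code array (0..S-1)."""
        codes = np.asarray(codes, dtype=np.intp)
        if codes.ndim != 2 or codes.shape[1] < 2:
            raise ValueError("codes must be (N, T) with T >= 2")
        if codes.size and (codes.min() < 0 or codes.max() >= state_space.n_states):
            raise ValueError("codes out of range for state space")
        obj = cls.__new__(cls)
        obj.state_space = state_space
        obj._codes = codes
        if subject_ids is None:
            subject_ids = [f"s{i + 1}" for i in range(codes.shape[0])]
        ids = tuple(str(s) for s in subject_ids)
        if len(ids) != codes.shape[0] or len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique and align with codes")
        obj.subject_ids = ids
        obj.outcomes = None if outcomes is None else np.asarray(outcomes, dtype=int)
        if obj.outcomes is not None and len(obj.outcomes) != codes.shape[0]:
            raise ValueError("outcomes do not align with codes")
        obj.covariates = None
        return obj

    @property
    def codes(self) -> np.ndarray:
        """(N, T) array of integer state codes."""
        return self._codes

    @property
    def n_subjects(self) -> int:
        return self._codes.shape[0]

    @property
    def n_visits(self) -> int:
        return self._codes.shape[1]

    @property
    def trajectories(self) -> list[Trajectory]:
        return [
            Trajectory(sid, self.state_space.decode(row))
            for sid, row in zip(self.subject_ids, self._codes)
        ]

    def __len__(self) -> int:
        return self.n_subjects

    def subset(self, mask_or_index: np.ndarray) -> "Cohort":
        """Row-subset (e.g. one cluster) preserving state space and outcomes."""
        idx = np.asarray(mask_or_index)
        out = self.outcomes[idx] if self.outcomes is not None else None
        ids = np.asarray(self.subject_ids, dtype=object)[idx]
        return Cohort.from_codes(self.state_space, self._codes[idx], ids, out)


def profile_count(state_space: StateSpace, n_visits: int) -> int:
    """Number of possible length-T profiles, S**T (e.g. 3**12 = 531441)."""
    if n_visits < 1:
        raise ValueError("need at least one visit")
    return state_space.n_states ** n_visits


def _clean_cell(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s else None


def read_cohort(
    source,
    layout: str = "wide",
    state_space: StateSpace | None = None,
    missing_policy: str = "recode_to_missing_label",
) -> Cohort:
    """Read a cohort from a wide or long CSV stream or path.

    Blank cells become the state space's missing label under
    ``missing_policy="recode_to_missing_label"``; under ``"error"`` any
    blank or unknown state code raises.
    """
    if state_space is None:
        state_space = default_state_space()
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    if missing_policy not in ("recode_to_missing_label", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    df = pd.read_csv(source, dtype=str, skipinitialspace=True)

    if layout == "wide":
        if df.shape[1] < 3:
            raise ValueError("wide cohort needs a subject column and >= 2 visits")
        subj_col = df.columns[0]
        visit_cols = list(df.columns[1:])
        rows = []
        for _, rec in df.iterrows():
            states = _resolve_states(
                [_clean_cell(rec[c]) for c in visit_cols],
                state_space,
                missing_policy,
                rec[subj_col],
            )
            rows.append(Trajectory(str(rec[subj_col]), states))
        return Cohort(state_space, rows)

    # long layout
    expected = {"subject", "visit", "state"}
    cols = {c.lower(): c for c in df.columns}
    if not expected <= set(cols):
        raise ValueError(f"long layout needs columns {sorted(expected)}")
    df = df.rename(columns={cols[k]: k for k in expected})
    df["visit"] = df["visit"].astype(int)
    if df.duplicated(["subject", "visit"]).any():
        dup = df[df.duplicated(["subject", "visit"], keep=False)]
        raise ValueError(
            f"duplicate (subject, visit) pairs: {dup[['subject', 'visit']].values[:5].tolist()}"
        )
    visits = np.sort(df["visit"].unique())
    T = len(visits)
    if T < 2:
        raise ValueError("need at least 2 visits")
    if visits[0] != 1 or visits[-1] != T:
        raise ValueError(f"visit indices must be contiguous 1..T, got {visits.tolist()}")
    rows = []
    for subj, grp in df.groupby("subject", sort=False):
        if len(grp) != T:
            raise ValueError(
                f"subject {subj!r} has {len(grp)} visits; cohort has {T}"
            )
        grp = grp.sort_values("visit")
        states = _resolve_states(
            [_clean_cell(v) for v in grp["state"]], state_space, missing_policy, subj
        )
        rows.append(Trajectory(str(subj), states))
    return Cohort(state_space, rows)


def _resolve_states(cells, space: StateSpace, policy: str, subject) -> tuple[str, ...]:
    out = []
    for cell in cells:
        if cell is None or cell not in space.labels:
            if policy == "error":
                raise ValueError(
                    f"subject {subject!r}: state {cell!r} not in {space.labels}"
                )
            if space.missing_label is None:
                raise ValueError(
                    f"subject {subject!r}: cannot recode {cell!r}; "
                    "state space has no missing label"
                )
            out.append(space.missing_label)
        else:
            out.append(cell)
    return tuple(out)


def read_outcomes(source, cohort: Cohort) -> np.ndarray:
    """Read a ``subject,event`` CSV and align events to cohort order."""
    df = pd.read_csv(source, dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "subject" not in cols or "event" not in cols:
        raise ValueError("outcome file needs columns subject,event")
    mapping: Mapping[str, int] = dict(
        zip(df[cols["subject"]].astype(str), df[cols["event"]].astype(int))
    )
    missing = [s for s in cohort.subject_ids if s not in mapping]
    if missing:
        raise ValueError(f"no outcome for subjects {missing[:5]}")
    events = np.array([mapping[s] for s in cohort.subject_ids], dtype=int)
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    return events


def write_assignments(cohort: Cohort, assignment, sink) -> None:
    """Write ``subject_id,cluster`` CSV; round-trips through read_assignments."""
    labels = np.asarray(getattr(assignment, "labels", assignment))
    if len(labels) != cohort.n_subjects:
        raise ValueError(
            f"{len(labels)} labels for {cohort.n_subjects} subjects"
        )
    df = pd.DataFrame({"subject_id": list(cohort.subject_ids), "cluster": labels})
    df.to_csv(sink, index=False)


def read_assignments(source) -> pd.DataFrame:
    """Read an assignments CSV back as a DataFrame (subject_id, cluster)."""
    df = pd.read_csv(source, dtype={"subject_id": str})
    if list(df.columns) != ["subject_id", "cluster"]:
        raise ValueError("assignments file needs columns subject_id,cluster")
    df["cluster"] = df["cluster"].astype(int)
    return df
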