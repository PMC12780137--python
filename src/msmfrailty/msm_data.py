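"""Long-format multistate event-history data for the illness-death model.

The canonical state space is 1 (healthy / transplant), 2 (ill / progression)
and 3 (death), with allowed transitions 1->2, 1->3 and 2->3; state 3 is
absorbing.  Data are held in "long" format: one row per individual per
transition they were at risk for, with an entry time, an exit time and an
event indicator, plus covariates and an optional cluster label for shared
frailty.  Intervals are half-open, ``(tstart, tstop]``: events happen at
``tstop``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: columns every long-format table must carry, in canonical order
CORE_COLUMNS = ["id", "from_state", "to_state", "tstart", "tstop", "status"]

#: tolerance used when checking path consistency of illness-death records
_TIME_ATOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Rows violate the multistate data invariants."""


@dataclass(frozen=True)
class TransitionStructure:
    """State space and allowed transitions of a progressive multistate model.

    Parameters
    ----------
    states
        Ordered state labels.  Defaults to ``(1, 2, 3)``.
    transitions
        Ordered allowed ``(from, to)`` pairs.  Defaults to the illness-death
        structure ``((1, 2), (1, 3), (2, 3))``.
    absorbing
        States with no outgoing transitions.  Defaults to ``(3,)``.
    """

    states: tuple[int, ...] = (1, 2, 3)
    transitions: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 3))
    absorbing: tuple[int, ...] = (3,)

    def __post_init__(self) -> None:
        for frm, to in self.transitions:
            if frm == to:
                raise ValueError(f"self-transition ({frm},{to}) not allowed")
            if frm not in self.states or to not in self.states:
                raise ValueError(f"transition ({frm},{to}) uses unknown state")
            if frm in self.absorbing:
                raise ValueError(f"transition out of absorbing state {frm}")

    def index(self, transition: tuple[int, int]) -> int:
        """Position of *transition* in the ordered transition list."""
        try:
            return self.transitions.index(tuple(transition))
        except ValueError:
            raise KeyError(f"unknown transition {transition}") from None

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


ILLNESS_DEATH = TransitionStructure()


@dataclass
class MultistateDataset:
    """Validated long-format event-history records.

    ``data`` holds one row per (individual, transition) with the core columns
    plus covariates and a ``cluster`` column.  ``time_kind`` distinguishes
    datasets on the original time scale from ones whose durations have been
    rescaled by individual-specific weights.
    """

    data: pd.DataFrame
    structure: TransitionStructure = field(default_factory=TransitionStructure)
    covariates: tuple[str, ...] = ()
    time_kind: str = "original"

    def __post_init__(self) -> None:
        if self.time_kind not in ("original", "weighted"):
            raise ValueError(f"time_kind must be original|weighted, got {self.time_kind!r}")
        self.data = self.data.reset_index(drop=True)
        if "cluster" not in self.data.columns:
            # univariate frailty by default: one cluster per subject
            self.data["cluster"] = self.data["id"]
        validate_records(self.data, self.structure)
        missing = [c for c in self.covariates if c not in self.data.columns]
        if missing:
            raise SchemaError(f"covariate columns missing from data: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].unique()

    def to_transition_view(
        self, transition: tuple[int, int], clock: str = "reset"
    ) -> pd.DataFrame:
        """Single-transition analysis table for individuals at risk.

        Returns one row per individual at risk for *transition*, with columns
        ``id, entry, duration, status, cluster`` and the covariates.  Under
        the default semi-Markov clock (``clock="reset"``) the sojourn clock
        restarts on state entry: ``entry = 0`` and
        ``duration = tstop - tstart``.  Under ``clock="forward"`` the study
        clock is kept: ``entry = tstart`` and ``duration = tstop`` (delayed
        entry / left truncation).
        """
        self.structure.index(transition)  # raises KeyError if unknown
        if clock not in ("reset", "forward"):
            raise ValueError(f"clock must be reset|forward, got {clock!r}")
        frm, to = transition
        sub = self.data[
            (self.data["from_state"] == frm) & (self.data["to_state"] == to)
        ].copy()
        if clock == "reset":
            sub["entry"] = 0.0
            sub["duration"] = sub["tstop"] - sub["tstart"]
        else:
            sub["entry"] = sub["tstart"]
            sub["duration"] = sub["tstop"]
        cols = ["id", "entry", "duration", "status", "cluster", *self.covariates]
        return sub[cols].reset_index(drop=True)

    def with_data(self, data: pd.DataFrame, time_kind: str | None = None) -> "MultistateDataset":
        """Copy of this dataset with new underlying records."""
        return MultistateDataset(
            data=data,
            structure=self.structure,
            covariates=self.covariates,
            time_kind=time_kind or self.time_kind,
        )


def validate_records(df: pd.DataFrame, structure: TransitionStructure) -> None:
    """Check the long-format invariants, raising ``ValidationError`` with
    offending row indices / ids on failure."""
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    bad = df.index[~df["status"].isin([0, 1])].tolist()
    if bad:
        raise ValidationError(f"status not in {{0,1}} at rows {bad}")

    bad = df.index[(df["tstart"] < 0) | ~(df["tstop"] > df["tstart"])].tolist()
    if bad:
        ids = df.loc[bad, "id"].tolist()
        raise ValidationError(
            f"require tstop > tstart >= 0; violated at rows {bad} (ids {ids})"
        )

    allowed = set(structure.transitions)
    pairs = list(zip(df["from_state"], df["to_state"]))
    bad = [i for i, p in zip(df.index, pairs) if p not in allowed]
    if bad:
        raise ValidationError(f"unknown transition pairs at rows {bad}")

    dup = df.duplicated(subset=["id", "from_state", "to_state"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate (id, transition) rows: {df.index[dup].tolist()}"
        )

    # illness-death path consistency: a 2->3 row requires a 1->2 event whose
    # exit time equals the 2->3 entry time
    if set(structure.transitions) == {(1, 2), (1, 3), (2, 3)}:
        ill = df[(df["from_state"] == 2) & (df["to_state"] == 3)]
        prog = df[(df["from_state"] == 1) & (df["to_state"] == 2)].set_index("id")
        for row in ill.itertuples():
            if row.id not in prog.index:
                raise ValidationError(f"id {row.id}: 2->3 record without a 1->2 record")
            p = prog.loc[row.id]
            if int(p["status"]) != 1:
                raise ValidationError(f"id {row.id}: 2->3 record but 1->2 not an event")
            if abs(float(p["tstop"]) - float(row.tstart)) > _TIME_ATOL:
                raise ValidationError(
                    f"id {row.id}: 2->3 entry {row.tstart} != 1->2 exit {p['tstop']}"
                )


DEFAULT_SCHEMA: Mapping[str, str] = {
    "id": "id",
    "from": "from_state",
    "to": "to_state",
    "tstart": "tstart",
    "tstop": "tstop",
    "status": "status",
}

#: column mapping for a CSV export of the ``ebmt3`` data from R's mstate
#: package (write.csv(ebmt3, ...)); times are converted from the paired
#: (prtime, prstat, rfstime, rfsstat) wide layout by :func:`read_ebmt3`.
EBMT3_COLUMNS = ("id", "prtime", "prstat", "rfstime", "rfsstat")


def read_long_format(
    path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    cluster: str | None = None,
    structure: TransitionStructure | None = None,
    sep: str = ",",
) -> MultistateDataset:
    """Read a delimited long-format file into a validated dataset.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Mapping from file column names to the canonical names
        ``id, from_state, to_state, tstart, tstop, status``.  Defaults to
        the identity mapping on ``id, from, to, tstart, tstop, status``.
    covariates
        Covariate column names (file names).  Defaults to every column not
        consumed by the schema or the cluster.
    cluster
        Column to use as the frailty cluster label; defaults to ``id``.
    """
    structure = structure or TransitionStructure()
    schema = dict(schema or DEFAULT_SCHEMA)
    raw = pd.read_csv(path, sep=sep)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"file {path} lacks required columns {missing}")
    df = raw.rename(columns=schema)
    if covariates is None:
        consumed = set(schema.values()) | {cluster or "", "cluster"}
        covariates = [c for c in df.columns if c not in consumed]
    if cluster is not None:
        if cluster not in df.columns:
            raise SchemaError(f"cluster column {cluster!r} not in file")
        df["cluster"] = df[cluster]
    keep = CORE_COLUMNS + (["cluster"] if "cluster" in df.columns else []) + list(covariates)
    return MultistateDataset(
        data=df[keep], structure=structure, covariates=tuple(covariates)
    )


def write_long_format(dataset: MultistateDataset, path, sep: str = ",") -> None:
    """Write a dataset as delimited text, full float precision, stable column order."""
    cols = CORE_COLUMNS + ["cluster", *dataset.covariates]
    df = dataset.data[cols].rename(
        columns={"from_state": "from", "to_state": "to"}
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_ebmt3(path, sep: str = ",") -> MultistateDataset:
    """Convert a CSV export of mstate's ``ebmt3`` data to long format.

    The export is wide: per patient, ``prtime``/``prstat`` give time and
    status of platelet recovery (state 2) and ``rfstime``/``rfsstat`` give
    relapse-free-survival time and status (state 3, absorbing).  Times are in
    days.  All remaining columns are carried as covariates.
    """
    raw = pd.read_csv(path, sep=sep)
    missing = [c for c in EBMT3_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"ebmt3 export lacks columns {missing}")
    covs = [c for c in raw.columns if c not in EBMT3_COLUMNS and c != "Unnamed: 0"]
    rows: list[dict] = []
    for r in raw.itertuples():
        base = {c: getattr(r, c) for c in covs}
        prtime, prstat = float(r.prtime), int(r.prstat)
        rfstime, rfsstat = float(r.rfstime), int(r.rfsstat)
        # guard zero-length intervals in the raw data
        prtime = max(prtime, 0.5)
        rfstime = max(rfstime, prtime + 0.5) if prstat else max(rfstime, 0.5)
        recovered = prstat == 1 and prtime < rfstime
        stop1 = prtime if recovered else rfstime
        rows.append({"id": r.id, "from_state": 1, "to_state": 2, "tstart": 0.0,
                     "tstop": stop1, "status": int(recovered), **base})
        rows.append({"id": r.id, "from_state": 1, "to_state": 3, "tstart": 0.0,
                     "tstop": stop1, "status": int(rfsstat and not recovered), **base})
        if recovered:
            rows.append({"id": r.id, "from_state": 2, "to_state": 3,
                         "tstart": prtime, "tstop": rfstime,
                         "status": int(rfsstat), **base})
    return MultistateDataset(data=pd.DataFrame(rows), covariates=tuple(covs))
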