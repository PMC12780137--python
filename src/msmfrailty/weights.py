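"""Individual-specific survival weights and weighted survival times.

For each transition i->j a Kaplan-Meier curve is fitted to the transition's
durations.  An individual's transition weight ``w_ij`` is that curve's
survival probability evaluated at the individual's own duration, using the
left limit S(t-) so that an individual's own event does not zero their
weight.  Cohort transition probabilities ``p_ij`` are the observed shares of
events on each transition (they sum to 1 across the three transitions by
construction).  Modified weights are ``w'_ij = w_ij * p_ij`` and each
individual's total weight is

    w_T = sum of w'_ij over the transitions the individual experienced,
          or 1 if they experienced no transition event.

Weighted survival times are the original times rescaled by w_T; statuses and
covariates are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .msm_data import MultistateDataset

__all__ = [
    "SurvivalCurve",
    "WeightTable",
    "kaplan_meier",
    "transition_probabilities",
    "individual_weights",
    "apply_weights",
    "combined_survival",
]

#: floor for rescaled durations, protecting downstream log / risk-set code
WEIGHTED_TIME_FLOOR = 1e-8


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function with risk-set bookkeeping."""

    times: np.ndarray      # distinct observed times, increasing
    survival: np.ndarray   # S(t) at each time (right-continuous)
    at_risk: np.ndarray    # number at risk just before each time
    events: np.ndarray     # events at each time

    def __post_init__(self) -> None:
        for name in ("times", "survival", "at_risk", "events"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def survival_at(self, t) -> np.ndarray:
        """S(t), right-continuous: the value after any event at t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def survival_before(self, t) -> np.ndarray:
        """Left limit S(t-): the value just before time t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def kaplan_meier(durations, statuses, entry=None) -> SurvivalCurve:
    """Product-limit estimator over the observed event times.

    ``entry`` (optional) gives delayed-entry times for left-truncated data.
    """
    durations = np.asarray(durations, dtype=float)
    statuses = np.asarray(statuses, dtype=float)
    if durations.size == 0:
        raise ValueError("empty input")
    if durations.shape != statuses.shape:
        raise ValueError("durations and statuses must have equal length")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=statuses, entry=entry)
    tab = kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row
    times = times[keep]
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)[keep]
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=float)[keep],
        events=tab["observed"].to_numpy(dtype=float)[keep],
    )


@dataclass
class WeightTable:
    """Per-(individual, transition) weights and per-individual totals.

    ``table`` has one row per at-risk (id, transition) with columns
    ``id, from_state, to_state, status, w, p, w_mod``; ``total`` maps id to
    the total weight w_T; ``p`` maps transition to its cohort probability.
    """

    table: pd.DataFrame
    total: pd.Series
    p: dict

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.p.values()), 1.0, atol=1e-12):
            raise ValueError("transition probabilities must sum to 1")
        if ((self.total <= 0) | (self.total > 1 + 1e-12)).any():
            raise ValueError("total weights must lie in (0, 1]")


def transition_probabilities(dataset: MultistateDataset, method: str = "events") -> dict:
    """Cohort transition probabilities p_ij, summing to 1 across transitions.

    ``method="events"`` (default) uses shares of observed transition events;
    ``method="records"`` uses shares of at-risk records instead.
    """
    if method not in ("events", "records"):
        raise ValueError(f"method must be events|records, got {method!r}")
    df = dataset.data
    counts = {}
    for tr in dataset.structure.transitions:
        sub = df[(df["from_state"] == tr[0]) & (df["to_state"] == tr[1])]
        counts[tr] = int(sub["status"].sum()) if method == "events" else len(sub)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no observed transition events; probabilities undefined")
    return {tr: counts[tr] / total for tr in counts}


def individual_weights(
    dataset: MultistateDataset, clock: str = "reset", p_method: str = "events"
) -> WeightTable:
    """Kaplan-Meier weights, modified weights and total weight per individual."""
    p = transition_probabilities(dataset, method=p_method)
    parts = []
    for tr in dataset.structure.transitions:
        view = dataset.to_transition_view(tr, clock=clock)
        if len(view) == 0:
            continue
        curve = kaplan_meier(
            view["duration"], view["status"],
            entry=view["entry"] if (view["entry"] > 0).any() else None,
        )
        w = curve.survival_before(view["duration"].to_numpy())
        parts.append(pd.DataFrame({
            "id": view["id"],
            "from_state": tr[0],
            "to_state": tr[1],
            "status": view["status"],
            "w": w,
            "p": p[tr],
            "w_mod": w * p[tr],
        }))
    table = pd.concat(parts, ignore_index=True)
    experienced = table[table["status"] == 1].groupby("id")["w_mod"].sum()
    total = pd.Series(1.0, index=pd.Index(dataset.ids, name="id"))
    total.loc[experienced.index] = experienced
    total = total.clip(lower=WEIGHTED_TIME_FLOOR, upper=1.0)
    return WeightTable(table=table, total=total, p=p)


def apply_weights(dataset: MultistateDataset, table: WeightTable) -> MultistateDataset:
    """Rescale every individual's times by their total weight w_T.

    Both interval endpoints are multiplied by w_T, preserving illness-death
    path consistency; statuses and covariates are unchanged.  Degenerate
    weighted durations are floored at ``WEIGHTED_TIME_FLOOR``.
    """
    df = dataset.data.copy()
    missing = set(df["id"]) - set(table.total.index)
    if missing:
        raise KeyError(f"weight table lacks ids: {sorted(missing)[:10]}")
    wt = table.total.loc[df["id"]].to_numpy()
    df["tstart"] = wt * df["tstart"].to_numpy()
    df["tstop"] = np.maximum(
        wt * df["tstop"].to_numpy(), df["tstart"].to_numpy() + WEIGHTED_TIME_FLOOR
    )
    return dataset.with_data(df, time_kind="weighted")


def combined_survival(
    dataset: MultistateDataset, table: WeightTable, times=None
) -> pd.DataFrame:
    """Per-individual weighted combination of the transition survival curves.

    For individual k the combined curve is ``sum_ij w'_kij S_ij(t)`` over the
    transitions k was at risk for, normalised by ``sum_ij w'_kij`` so it
    starts at 1.  A read-only report; the fitting pipeline uses weighted
    times, not this curve.
    """
    curves = {}
    for tr in dataset.structure.transitions:
        view = dataset.to_transition_view(tr)
        if len(view):
            curves[tr] = kaplan_meier(view["duration"], view["status"])
    if times is None:
        times = np.unique(np.concatenate([c.times for c in curves.values()]))
    times = np.asarray(times, dtype=float)
    tab = table.table
    out = {}
    for id_, grp in tab.groupby("id"):
        num = np.zeros_like(times)
        den = 0.0
        for row in grp.itertuples():
            tr = (int(row.from_state), int(row.to_state))
            num += row.w_mod * curves[tr].survival_at(times)
            den += row.w_mod
        out[id_] = num / den if den > 0 else np.ones_like(times)
    return pd.DataFrame(out, index=pd.Index(times, name="time")).T
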