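"""Replicate simulation-study harness: bias/MSE of coefficients and frailty
variances under unweighted vs weighted survival times.

One replicate is: simulate an illness-death dataset, fit the per-transition
frailty Cox models on the original times, compute individual-specific
survival weights, rescale the times, and refit on the weighted times.
Estimates are aggregated across replicates into mean, MSE and bias against
the generating coefficients; MSE is the mean squared deviation from truth,
so MSE = variance + bias^2 holds cell-wise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frailty_fit import FitControl, fit_msm
from .msm_data import MultistateDataset, read_long_format
from .simulator import SimConfig, simulate_dataset
from .weights import apply_weights, individual_weights

__all__ = [
    "StudyReport",
    "replicate_metrics",
    "run_simulation_study",
    "bias_summary_export",
    "plot_bias_boxplots",
    "run_real_data",
]

logger = logging.getLogger("msmfrailty")

_TIME_KINDS = ("unweighted", "weighted")


def replicate_metrics(estimates, truth: float) -> tuple[float, float, float]:
    """(mean, MSE, bias) of replicate estimates against the true value.

    mean = average estimate; bias = mean - truth;
    MSE  = average of (estimate - truth)^2.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    mean = float(est.mean())
    bias = mean - truth
    mse = float(np.mean((est - truth) ** 2))
    return mean, mse, bias


@dataclass
class StudyReport:
    """Aggregated simulation-study results.

    ``summary``: one row per (time_kind, transition, covariate) with
    mean/MSE/bias columns.  ``sigma2``: mean estimated frailty variance per
    (time_kind, transition).  ``raw``: per-replicate estimates, long format.
    """

    summary: pd.DataFrame
    sigma2: pd.DataFrame
    raw: pd.DataFrame
    config: SimConfig
    n_replicates: int
    n_failed: int = 0
    failures: list = field(default_factory=list)


def _transition_label(tr: tuple[int, int]) -> str:
    return f"{tr[0]}->{tr[1]}"


def run_simulation_study(
    config: SimConfig,
    R: int | None = None,
    control: FitControl = FitControl(),
) -> StudyReport:
    """Run the full replicate study (simulate, fit, weight, refit, aggregate).

    Replicate r uses seed ``config.seed + r``.  Replicates where any fit
    fails are excluded, with the failure count reported.
    """
    R = config.replicates if R is None else R
    rows: list[dict] = []
    failures: list[str] = []
    for r in range(R):
        try:
            dataset, _ = simulate_dataset(config, seed=config.seed + r)
            datasets = {"unweighted": dataset}
            wt = individual_weights(dataset)
            datasets["weighted"] = apply_weights(dataset, wt)
            for kind, ds in datasets.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits = fit_msm(ds, control=control)
                for tr, fit in fits.items():
                    if fit is None:
                        continue
                    for cov in ds.covariates:
                        rows.append({
                            "replicate": r, "time_kind": kind,
                            "transition": _transition_label(tr), "covariate": cov,
                            "estimate": float(fit.beta[cov]),
                            "truth": float(config.true_beta[tr][
                                list(config.covariate_names).index(cov)]),
                        })
                    rows.append({
                        "replicate": r, "time_kind": kind,
                        "transition": _transition_label(tr), "covariate": "sigma2",
                        "estimate": fit.sigma2, "truth": np.nan,
                    })
        except Exception as exc:  # noqa: BLE001 - a replicate may legitimately fail
            failures.append(f"replicate {r}: {exc}")
            logger.warning("replicate %d failed: %s", r, exc)
    raw = pd.DataFrame(rows)
    if raw.empty:
        raise RuntimeError("all replicates failed: " + "; ".join(failures[:3]))

    coef = raw[raw["covariate"] != "sigma2"]
    recs = []
    for (kind, tr, cov), grp in coef.groupby(["time_kind", "transition", "covariate"]):
        mean, mse, bias = replicate_metrics(grp["estimate"], grp["truth"].iloc[0])
        recs.append({
            "time_kind": kind, "transition": tr, "covariate": cov,
            "truth": grp["truth"].iloc[0], "mean": mean, "mse": mse, "bias": bias,
            "n": len(grp),
        })
    summary = pd.DataFrame(recs)

    sig = raw[raw["covariate"] == "sigma2"]
    sigma2 = (
        sig.groupby(["time_kind", "transition"])["estimate"]
        .agg(["mean", "median", "count"])
        .reset_index()
        .rename(columns={"mean": "sigma2_mean", "median": "sigma2_median", "count": "n"})
    )
    return StudyReport(
        summary=summary, sigma2=sigma2, raw=raw, config=config,
        n_replicates=R, n_failed=len(failures), failures=failures,
    )


def bias_summary_export(report: StudyReport) -> pd.DataFrame:
    """Long table of per-replicate biases, one row per
    (transition, covariate, time_kind, replicate) — boxplot-ready."""
    coef = report.raw[report.raw["covariate"] != "sigma2"].copy()
    coef["bias"] = coef["estimate"] - coef["truth"]
    return coef[["transition", "covariate", "time_kind", "replicate", "bias"]].reset_index(
        drop=True
    )


def plot_bias_boxplots(report: StudyReport, path=None):
    """Grouped boxplots of per-replicate coefficient bias (matplotlib axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    long = bias_summary_export(report)
    transitions = sorted(long["transition"].unique())
    fig, axes = plt.subplots(1, len(transitions), figsize=(4 * len(transitions), 4),
                             sharey=True, squeeze=False)
    for ax, tr in zip(axes[0], transitions):
        sub = long[long["transition"] == tr]
        covs = sorted(sub["covariate"].unique())
        data, labels = [], []
        for cov in covs:
            for kind in _TIME_KINDS:
                data.append(sub[(sub["covariate"] == cov)
                                & (sub["time_kind"] == kind)]["bias"].to_numpy())
                labels.append(f"{cov}\n{kind[0]}")
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(tr)
        ax.set_ylabel("bias")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def run_real_data(
    path,
    cluster: str | None = None,
    control: FitControl = FitControl(),
    arm_seed: int = 0,
    reader=None,
) -> dict[str, dict]:
    """Per-transition frailty Cox coefficient tables for a user-supplied
    long-format dataset, on original and weighted times.

    Adds a seeded binomial ``arm`` covariate when the data lack one (the
    comparison-arm column of the transplant-registry analysis is synthetic by
    construction).  Returns ``{"unweighted": {...}, "weighted": {...}}``
    where each inner mapping sends a transition label to a coefficient table
    with coef, SE, HR and 95% CI plus the estimated frailty variance.
    """
    if isinstance(path, MultistateDataset):
        dataset = path
    else:
        dataset = (reader or read_long_format)(path)
    if "arm" not in dataset.data.columns:
        rng = np.random.default_rng(arm_seed)
        ids = dataset.ids
        arm = pd.Series(rng.binomial(1, 0.5, size=len(ids)), index=ids)
        df = dataset.data.copy()
        df["arm"] = arm.loc[df["id"]].to_numpy()
        dataset = MultistateDataset(
            data=df, structure=dataset.structure,
            covariates=tuple(dataset.covariates) + ("arm",),
            time_kind=dataset.time_kind,
        )
    if cluster is not None:
        df = dataset.data.copy()
        df["cluster"] = df[cluster]
        dataset = dataset.with_data(df)

    out: dict[str, dict] = {}
    wt = individual_weights(dataset)
    for kind, ds in (("unweighted", dataset), ("weighted", apply_weights(dataset, wt))):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_msm(ds, control=control)
        tables = {}
        for tr, fit in fits.items():
            if fit is None:
                continue
            tab = fit.summary()
            tab.attrs["sigma2"] = fit.sigma2
            tables[_transition_label(tr)] = tab
        out[kind] = tables
    return out
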