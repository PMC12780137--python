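"""Transition-specific Cox proportional-hazards fitting with shared gamma frailty.

The conditional hazard of a cluster with frailty Z on transition i->j is
``h(t | x, Z) = Z h0(t) exp(beta'x)``.  Estimation follows the classical EM
scheme for the semi-parametric shared gamma frailty model:

* M-step: a Cox partial-likelihood Newton fit with the current log-frailties
  as per-row offsets (Breslow tie handling), followed by a Breslow estimate
  of the cumulative baseline hazard;
* E-step: the gamma posterior mean of each cluster's frailty,
  ``Z_c = (1/s2 + d_c) / (1/s2 + sum_k H0(t_k) exp(beta'x_k))``;
* the frailty variance ``s2`` is profiled on the marginal (unconditional)
  gamma-frailty log-likelihood, maximised by a bracketing grid scan plus
  golden-section search on log s2.

EM convergence is declared when the relative change of the marginal
log-likelihood falls below ``em_tol``.  Standard errors for beta come from
the inverse observed information of the final offset-Cox stage, i.e. they
condition on the estimated frailties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .msm_data import MultistateDataset

__all__ = [
    "FitControl",
    "CoxResult",
    "BreslowBaseline",
    "FrailtyFit",
    "cox_partial_fit",
    "breslow_baseline",
    "estimate_frailties",
    "gamma_marginal_loglik",
    "fit_transition_frailty",
    "fit_msm",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitControl:
    """Tolerances and search ranges of the frailty fit."""

    em_tol: float = 1e-6          # relative marginal-loglik change
    em_max_iter: int = 200
    newton_tol: float = 1e-8      # max |score| at the Cox stage
    newton_max_iter: int = 100
    sigma2_floor: float = 1e-4
    sigma2_ceiling: float = 50.0
    n_grid: int = 9               # coarse log-spaced bracket scan
    golden_tol: float = 0.01      # on log sigma2


# ---------------------------------------------------------------------------
# Cox partial likelihood with offsets (Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float          # partial log-likelihood at beta
    info: np.ndarray       # observed information (negative Hessian)
    n_iter: int
    converged: bool


class _CoxData:
    """Pre-sorted arrays for one transition view; reused across EM iterations."""

    def __init__(self, view: pd.DataFrame, covariates) -> None:
        self.covariates = list(covariates)
        dur = view["duration"].to_numpy(float)
        order = np.argsort(dur, kind="stable")
        self.order = order
        self.dur = dur[order]
        self.status = view["status"].to_numpy(float)[order]
        self.entry = (
            view["entry"].to_numpy(float)[order]
            if "entry" in view.columns else np.zeros_like(self.dur)
        )
        self.X = view[self.covariates].to_numpy(float)[order]
        self.n, self.p = self.X.shape
        self.event_times, inv = np.unique(self.dur[self.status == 1], return_inverse=True)
        self.d = np.bincount(inv).astype(float)  # events per unique time
        self.n_events = int(self.status.sum())
        # first sorted index at risk for each unique event time (entry==0 path)
        self.start_idx = np.searchsorted(self.dur, self.event_times, side="left")
        self.trivial_entry = not np.any(self.entry > 0)

    def risk_sums(self, w: np.ndarray):
        """S0, S1, S2 over the risk set of each unique event time.

        ``w`` are per-row weights exp(eta).  S1 has shape (E, p), S2 (E, p, p).
        """
        Xw = self.X * w[:, None]
        XXw = np.einsum("ni,nj,n->nij", self.X, self.X, w)
        if self.trivial_entry:
            s0 = np.cumsum(w[::-1])[::-1]
            s1 = np.cumsum(Xw[::-1], axis=0)[::-1]
            s2 = np.cumsum(XXw[::-1], axis=0)[::-1]
            return s0[self.start_idx], s1[self.start_idx], s2[self.start_idx]
        E = len(self.event_times)
        S0 = np.empty(E)
        S1 = np.empty((E, self.p))
        S2 = np.empty((E, self.p, self.p))
        for e, t in enumerate(self.event_times):
            mask = (self.entry < t) & (self.dur >= t)
            S0[e] = w[mask].sum()
            S1[e] = Xw[mask].sum(axis=0)
            S2[e] = XXw[mask].sum(axis=0)
        return S0, S1, S2

    def risk_s0(self, w: np.ndarray) -> np.ndarray:
        if self.trivial_entry:
            return np.cumsum(w[::-1])[::-1][self.start_idx]
        return np.array([
            w[(self.entry < t) & (self.dur >= t)].sum() for t in self.event_times
        ])


def _newton(data: _CoxData, offset: np.ndarray, beta0, control: FitControl) -> CoxResult:
    beta = np.zeros(data.p) if beta0 is None else np.asarray(beta0, float).copy()
    ev = data.status == 1
    ll_prev = -np.inf
    for it in range(1, control.newton_max_iter + 1):
        eta = data.X @ beta + offset
        eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
        w = np.exp(eta)
        S0, S1, S2 = data.risk_sums(w)
        ll = float(eta[ev].sum() - (data.d * np.log(S0)).sum())
        mean = S1 / S0[:, None]
        grad = data.X[ev].sum(axis=0) - (data.d[:, None] * mean).sum(axis=0)
        info = np.einsum("e,eij->ij", data.d, S2 / S0[:, None, None]) - np.einsum(
            "e,ei,ej->ij", data.d, mean, mean
        )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix (collinear covariates?)")
        if np.max(np.abs(grad)) < control.newton_tol:
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return CoxResult(beta, se, ll, info, it, True)
        # damped update: halve until the partial likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = data.X @ cand + offset
            eta_c -= eta_c.max()
            w_c = np.exp(eta_c)
            ll_c = float(eta_c[ev].sum() - (data.d * np.log(data.risk_s0(w_c))).sum())
            if ll_c >= ll - 1e-10 * (1.0 + abs(ll)):  # tolerate float noise in ties
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_prev = ll
    raise ConvergenceError(
        f"Cox Newton did not reach |score| < {control.newton_tol} "
        f"in {control.newton_max_iter} iterations"
    )


def cox_partial_fit(
    view: pd.DataFrame,
    covariates,
    offsets=None,
    beta0=None,
    control: FitControl = FitControl(),
) -> CoxResult:
    """Maximise the Breslow-ties Cox partial likelihood with fixed offsets.

    ``view`` is a transition table with columns ``duration``, ``status``,
    optionally ``entry`` (delayed entry), and the covariates.
    """
    data = _CoxData(view, covariates)
    if data.n_events == 0:
        raise ValueError("no events in view; Cox fit undefined")
    offset = np.zeros(data.n) if offsets is None else np.asarray(offsets, float)[data.order]
    return _newton(data, offset, beta0, control)


# ---------------------------------------------------------------------------
# Breslow baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreslowBaseline:
    """Nonparametric cumulative baseline hazard: jumps at event times.

    ``H0(t) = sum over event times s <= t of d_s / sum_{k at risk at s}
    Z_k exp(beta'x_k)``.
    """

    times: np.ndarray
    jumps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_cum", np.concatenate([[0.0], np.cumsum(self.jumps)])
        )

    @property
    def cumulative(self) -> np.ndarray:
        return self._cum[1:]

    def cumulative_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return self._cum[idx]

    def jump_at(self, t) -> np.ndarray:
        """Jump size at exactly t (0 between event times)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        idx = np.clip(idx, 0, len(self.times) - 1)
        out = np.where(np.isclose(self.times[idx], t), self.jumps[idx], 0.0)
        return out


def _breslow(data: _CoxData, beta: np.ndarray, offset: np.ndarray) -> BreslowBaseline:
    w = np.exp(data.X @ beta + offset)
    S0 = data.risk_s0(w)
    return BreslowBaseline(times=data.event_times.copy(), jumps=data.d / S0)


def breslow_baseline(view, covariates, beta, frailties=None) -> BreslowBaseline:
    """Breslow cumulative baseline given beta and (optional) per-row frailties."""
    data = _CoxData(view, covariates)
    z = np.ones(data.n) if frailties is None else np.asarray(frailties, float)[data.order]
    return _breslow(data, np.asarray(beta, float), np.log(z))


# ---------------------------------------------------------------------------
# E-step and marginal likelihood
# ---------------------------------------------------------------------------

class _ClusterData:
    """Cached per-view arrays for the E-step and marginal likelihood."""

    def __init__(self, view: pd.DataFrame, covariates) -> None:
        self.codes, self.labels = pd.factorize(view["cluster"], sort=True)
        self.n_clusters = len(self.labels)
        self.X = view[list(covariates)].to_numpy(float)
        self.dur = view["duration"].to_numpy(float)
        self.entry = (
            view["entry"].to_numpy(float) if "entry" in view.columns
            else np.zeros_like(self.dur)
        )
        self.status = view["status"].to_numpy(float)
        self.ev = self.status == 1
        self.d = np.bincount(self.codes, weights=self.status, minlength=self.n_clusters)

    def hazard_sums(self, beta, H0: BreslowBaseline) -> np.ndarray:
        """A_c = sum_k [H0(t_k) - H0(entry_k)] exp(beta'x_k) per cluster."""
        risk = (H0.cumulative_at(self.dur) - H0.cumulative_at(self.entry)) * np.exp(
            self.X @ np.asarray(beta, float)
        )
        return np.bincount(self.codes, weights=risk, minlength=self.n_clusters)

    def posterior_frailty(self, beta, H0: BreslowBaseline, sigma2: float) -> np.ndarray:
        inv = 1.0 / sigma2
        return (inv + self.d) / (inv + self.hazard_sums(beta, H0))

    def marginal_loglik(self, beta, sigma2: float, H0: BreslowBaseline) -> float:
        inv = 1.0 / sigma2
        A = self.hazard_sums(beta, H0)
        cluster_terms = (
            self.d * math.log(sigma2)
            + gammaln(inv + self.d)
            - gammaln(inv)
            - (inv + self.d) * np.log1p(sigma2 * A)
        )
        h0 = H0.jump_at(self.dur[self.ev])
        if np.any(h0 <= 0):
            raise ValueError("zero Breslow increment at an event time")
        event_terms = (self.X[self.ev] @ np.asarray(beta, float)).sum() + np.log(h0).sum()
        return float(cluster_terms.sum() + event_terms)


def _cluster_sums(view, covariates, beta, H0: BreslowBaseline):
    """Per-cluster event counts d_c and hazard sums A_c = sum H0(t_k) e^{beta'x_k}.

    With delayed entry the contribution is H0(duration) - H0(entry).
    """
    cd = _ClusterData(view, covariates)
    return cd.codes, cd.labels, cd.d, cd.hazard_sums(beta, H0)


def estimate_frailties(view, covariates, beta, H0: BreslowBaseline, sigma2: float) -> pd.Series:
    """Gamma posterior mean of each cluster's frailty,
    ``(1/s2 + d_c) / (1/s2 + A_c)``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    cd = _ClusterData(view, covariates)
    return pd.Series(
        cd.posterior_frailty(beta, H0, sigma2),
        index=pd.Index(cd.labels, name="cluster"),
    )


def gamma_marginal_loglik(view, covariates, beta, sigma2: float, H0: BreslowBaseline) -> float:
    """Marginal (unconditional) log-likelihood of the gamma frailty model.

    Per cluster c with d_c events and hazard sum A_c:

        d_c log s2 + lgamma(1/s2 + d_c) - lgamma(1/s2)
        - (1/s2 + d_c) log(1 + s2 A_c)
        + sum over events (beta'x_k + log h0(t_k))

    where log h0 uses the Breslow jump at the event time.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return _ClusterData(view, covariates).marginal_loglik(beta, sigma2, H0)


# ---------------------------------------------------------------------------
# Full fit: EM inside a profile search over sigma2
# ---------------------------------------------------------------------------

@dataclass
class FrailtyFit:
    """Converged frailty Cox fit for one transition."""

    transition: tuple[int, int] | None
    covariates: tuple[str, ...]
    beta: pd.Series
    se: pd.Series
    sigma2: float
    frailty: pd.Series              # posterior means Z_c per cluster
    baseline: BreslowBaseline
    loglik: float                   # maximised marginal log-likelihood
    n_iter: int                     # EM iterations at the final sigma2
    converged: bool
    profile: list = field(default_factory=list)  # (sigma2, loglik) pairs visited
    message: str = ""

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: coef, SE, HR with a 95% Wald interval."""
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return pd.DataFrame({
            "coef": self.beta, "se": self.se, "HR": np.exp(self.beta),
            "HR_lower95": lo, "HR_upper95": hi,
        })


def _em(data: _CoxData, cdata: _ClusterData, sigma2, beta, Z_rows, control):
    """Run EM at fixed sigma2 from a warm start; returns the converged state."""
    ll_prev = None
    for it in range(1, control.em_max_iter + 1):
        offset_sorted = np.log(Z_rows)[data.order]
        cox = _newton(data, offset_sorted, beta, control)
        beta = cox.beta
        H0 = _breslow(data, beta, offset_sorted)
        Z_cluster = cdata.posterior_frailty(beta, H0, sigma2)
        Z_rows = Z_cluster[cdata.codes]
        ll = cdata.marginal_loglik(beta, sigma2, H0)
        if ll_prev is not None and abs(ll - ll_prev) <= control.em_tol * (abs(ll_prev) + 1e-12):
            return ll, beta, Z_rows, Z_cluster, H0, cox, it, True
        ll_prev = ll
    return ll, beta, Z_rows, Z_cluster, H0, cox, control.em_max_iter, False


def fit_transition_frailty(
    view: pd.DataFrame,
    covariates,
    control: FitControl = FitControl(),
    transition: tuple[int, int] | None = None,
) -> FrailtyFit:
    """Fit the shared gamma frailty Cox model on one transition view.

    The frailty variance is profiled: the marginal log-likelihood is scanned
    on a log-spaced grid over ``[sigma2_floor, sigma2_ceiling]`` and refined
    by golden-section search between the best grid point's neighbours; the EM
    warm-starts from the previous evaluation.
    """
    covariates = tuple(covariates)
    data = _CoxData(view, covariates)
    cdata = _ClusterData(view, covariates)
    if data.n_events == 0:
        raise ValueError("no events in view; frailty fit undefined")
    n_clusters = cdata.n_clusters

    state = {"beta": None, "Z": np.ones(len(view))}
    cache: dict[float, tuple] = {}

    def profile(log_s2: float):
        s2 = math.exp(log_s2)
        if log_s2 in cache:
            return cache[log_s2]
        res = _em(data, cdata, s2, state["beta"], state["Z"], control)
        state["beta"], state["Z"] = res[1], res[2]
        cache[log_s2] = (res[0], s2, res)
        return cache[log_s2]

    message = ""
    if n_clusters < 2:
        message = "fewer than 2 clusters: sigma2 fixed at the floor (not identifiable)"
        warnings.warn(message)
        best_log = math.log(control.sigma2_floor)
        profile(best_log)
    else:
        lo, hi = math.log(control.sigma2_floor), math.log(control.sigma2_ceiling)
        grid = np.linspace(lo, hi, control.n_grid)
        lls = [profile(g)[0] for g in grid]
        k = int(np.argmax(lls))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        # golden-section maximisation of the profile on [a, b]
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        c, dpt = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = profile(c)[0], profile(dpt)[0]
        while b - a > control.golden_tol:
            if fc >= fd:
                b, dpt, fd = dpt, c, fc
                c = b - invphi * (b - a)
                fc = profile(c)[0]
            else:
                a, c, fc = c, dpt, fd
                dpt = a + invphi * (b - a)
                fd = profile(dpt)[0]
        best_log = max(cache, key=lambda g: cache[g][0])

    ll, s2, res = cache[best_log]
    _, beta, _, Z_cluster, H0, cox, n_iter, em_ok = res
    frailty = pd.Series(Z_cluster, index=pd.Index(cdata.labels, name="cluster"))
    fit = FrailtyFit(
        transition=transition,
        covariates=covariates,
        beta=pd.Series(beta, index=list(covariates), name="coef"),
        se=pd.Series(cox.se, index=list(covariates), name="se"),
        sigma2=s2,
        frailty=frailty,
        baseline=H0,
        loglik=ll,
        n_iter=n_iter,
        converged=em_ok and cox.converged,
        profile=sorted((v[1], v[0]) for v in cache.values()),
        message=message,
    )
    if not fit.converged:
        warnings.warn(f"frailty fit did not fully converge (transition {transition})")
    return fit


def fit_msm(
    dataset: MultistateDataset,
    cluster: str | None = None,
    control: FitControl = FitControl(),
    clock: str = "reset",
) -> dict[tuple[int, int], FrailtyFit | None]:
    """Independent frailty Cox fits for every transition of the dataset.

    ``cluster`` optionally nominates a column to use as the frailty cluster
    (default: the dataset's own cluster column, i.e. the individual id unless
    set otherwise).  Transitions with no events map to ``None`` (skipped).
    """
    ds = dataset
    if cluster is not None:
        if cluster not in dataset.data.columns:
            raise KeyError(f"cluster column {cluster!r} not in dataset")
        df = dataset.data.copy()
        df["cluster"] = df[cluster]
        ds = dataset.with_data(df)
    fits: dict[tuple[int, int], FrailtyFit | None] = {}
    for tr in ds.structure.transitions:
        view = ds.to_transition_view(tr, clock=clock)
        if len(view) == 0 or view["status"].sum() == 0:
            warnings.warn(f"transition {tr}: no events; skipped")
            fits[tr] = None
            continue
        fits[tr] = fit_transition_frailty(
            view, ds.covariates, control=control, transition=tr
        )
    return fits
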