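"""Survival-analysis engines.

Implements the four estimators the index pipeline is built on:

* :func:`fit_cox` — Cox proportional-hazards regression by Newton
  maximisation of the Efron (default) or Breslow partial likelihood;
* :func:`km` — the Kaplan–Meier product-limit survival estimator;
* :func:`cuminc` — the Aalen–Johansen cumulative-incidence estimator for
  competing risks (cancer death vs other-cause death);
* :func:`td_auc` — the incident/dynamic time-dependent AUC of Heagerty &
  Zheng, with the concordance-weighted integrated summary.

All estimators are deterministic, operate on plain numpy arrays or pandas
containers, and evaluate step functions right-continuously.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FittedCox",
    "StepFunction",
    "CIFEstimate",
    "fit_cox",
    "km",
    "cuminc",
    "td_auc",
    "auc_se",
]


# ---------------------------------------------------------------------------
# step functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with value ``init`` before the first knot."""

    x: np.ndarray
    y: np.ndarray
    init: float = 1.0

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if len(self.x) == 0:
            out = np.full(t.shape, self.init)
        else:
            idx = np.searchsorted(self.x, t, side=side) - 1
            out = np.where(idx >= 0, self.y[np.clip(idx, 0, len(self.y) - 1)], self.init)
        return float(out) if out.ndim == 0 else out

    def __call__(self, t):
        return self._eval(t, "right")

    def left_limit(self, t):
        """Value just before ``t`` (left-continuous evaluation)."""
        return self._eval(t, "left")


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


@dataclass
class FittedCox:
    """A fitted Cox proportional-hazards model.

    ``coef`` are log hazard ratios; ``hazard_ratios`` is ``exp(coef)``.
    ``converged`` reports whether the gradient tolerance was met within the
    iteration cap; separation (monotone likelihood) is surfaced through
    ``warnings_`` rather than an exception.
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    n_iter: int
    grad_norm: float
    converged: bool
    ties: str = "efron"
    warnings_: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def coef_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.terms, name="coef")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": np.exp(self.coef),
                "z": self.coef / self.se,
            },
            index=pd.Index(self.terms, name="term"),
        )


def _efron_loglik_grad_hess(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    ties: str,
    want_hess: bool,
):
    """One pass over the data: log partial likelihood, gradient, information.

    Subjects are processed in decreasing time order so the risk set grows by
    accumulation; per-event-time aggregates implement Efron's (or Breslow's)
    correction for tied event times.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta -= eta.max()  # guard exp overflow; constant shift cancels everywhere
    w = np.exp(eta)

    event_times = np.unique(ts[es])[::-1]  # descending
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p)) if want_hess else None

    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p)) if want_hess else None
    ptr = 0

    for t_e in event_times:
        while ptr < n and ts[ptr] >= t_e:
            stop = ptr
            while stop < n and ts[stop] >= t_e:
                stop += 1
            block = slice(ptr, stop)
            wb = w[block]
            Xb = Xs[block]
            S0 += wb.sum()
            S1 += wb @ Xb
            if want_hess:
                S2 += Xb.T @ (Xb * wb[:, None])
            ptr = stop
        mask = (ts == t_e) & es
        # relies on contiguity of the sorted block; use boolean mask on sorted arrays
        d = int(mask.sum())
        we = w[mask]
        Xe = Xs[mask]
        s0_t = we.sum()
        s1_t = we @ Xe
        if ties == "efron":
            frac = np.arange(d) / d
        else:  # breslow
            frac = np.zeros(d)
        denom = S0 - frac * s0_t  # (d,)
        loglik += eta[mask].sum() - np.log(denom).sum()
        num = S1[None, :] - frac[:, None] * s1_t[None, :]  # (d, p)
        grad += Xe.sum(axis=0) - (num / denom[:, None]).sum(axis=0)
        if want_hess:
            s2_t = Xe.T @ (Xe * we[:, None])
            inv = 1.0 / denom
            term1 = S2 * inv.sum() - s2_t * (frac * inv).sum()
            term2 = np.einsum("j,jp,jq->pq", inv**2, num, num)
            info += term1 - term2

    # the eta max-shift cancels between event terms and log-denominators,
    # so loglik is the true log partial likelihood
    return loglik, grad, info


def fit_cox(
    X,
    time,
    event,
    ties: str = "efron",
    tol_grad: float = 1e-8,
    tol_loglik: float = 1e-10,
    max_iter: int = 100,
    coef_cap: float = 25.0,
) -> FittedCox:
    """Fit a Cox proportional-hazards model by maximum partial likelihood.

    Parameters
    ----------
    X
        Design matrix, ``(n, p)``; a :class:`pandas.DataFrame` supplies term
        names. Columns must be non-constant and pairwise distinct.
    time, event
        Follow-up time and event indicator (1 = event of interest; 0 =
        censored, which includes deaths from the competing cause when
        building the index).
    ties
        ``"efron"`` (default) or ``"breslow"`` tie handling.

    Raises
    ------
    ValueError
        If there are no events, or the design contains constant or
        duplicate (exactly collinear) columns.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        terms = [f"x{i}" for i in range(Xa.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    if event.sum() == 0:
        raise ValueError("no events: partial likelihood is undefined")
    if np.any(time < 0):
        raise ValueError("negative follow-up time")

    # column validation: constant and duplicate columns make the information
    # matrix singular and are programming errors upstream
    ptp = Xa.max(axis=0) - Xa.min(axis=0)
    if np.any(ptp == 0):
        bad = [terms[i] for i in np.flatnonzero(ptp == 0)]
        raise ValueError(f"constant column(s) in design: {bad}")
    _, first_idx = np.unique(Xa, axis=1, return_index=True)
    if len(first_idx) < Xa.shape[1]:
        dup = sorted(set(range(Xa.shape[1])) - set(first_idx))
        raise ValueError(f"duplicate column(s) in design: {[terms[i] for i in dup]}")

    means = Xa.mean(axis=0)
    Xc = Xa - means  # centering stabilises exp(eta); coefficients unchanged

    p = Xc.shape[1]
    beta = np.zeros(p)
    loglik, grad, info = _efron_loglik_grad_hess(Xc, time, event, beta, ties, True)
    msgs: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
            msgs.append("singular information matrix; least-squares step used")
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _efron_loglik_grad_hess(
                Xc, time, event, cand, ties, True
            )
            if ll_new >= loglik - 1e-12:
                break
            factor *= 0.5
        rel_change = abs(ll_new - loglik) / max(1.0, abs(loglik))
        beta, grad, info = cand, grad_new, info_new
        loglik_prev, loglik = loglik, ll_new
        if np.max(np.abs(beta)) > coef_cap:
            msg = (
                "monotone partial likelihood suspected (separation): "
                f"|coef| exceeded {coef_cap}; estimates capped at iteration {it}"
            )
            msgs.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            break
        if np.max(np.abs(grad)) < tol_grad or rel_change < tol_loglik:
            converged = True
            break

    if np.max(np.abs(beta)) > 10.0 and not any("separation" in m for m in msgs):
        # hazard ratios beyond e^10 signal a monotone likelihood flattening
        # out rather than a real effect
        msg = "monotone partial likelihood suspected (separation): |coef| > 10"
        msgs.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    if not converged and not msgs:
        msgs.append(f"did not converge in {max_iter} iterations")
    return FittedCox(
        terms=terms,
        coef=beta,
        se=se,
        cov=cov,
        log_likelihood=float(loglik),
        n_iter=it,
        grad_norm=float(np.max(np.abs(grad))),
        converged=converged,
        ties=ties,
        warnings_=msgs,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km(time, event) -> StepFunction:
    """Kaplan–Meier product-limit estimator of the survival function."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise ValueError("empty sample")
    uniq, d = np.unique(time[event], return_counts=True)
    if len(uniq) == 0:
        return StepFunction(x=np.array([]), y=np.array([]), init=1.0)
    st = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(st, uniq, side="left")
    surv = np.cumprod(1.0 - d / n_at_risk)
    return StepFunction(x=uniq, y=surv, init=1.0)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------


@dataclass
class CIFEstimate:
    """Nonparametric cumulative incidence for competing causes of death.

    ``cif[cause](t)`` is the probability of having died of ``cause`` by
    ``t``; ``survival(t)`` is all-cause Kaplan–Meier survival. At every
    ``t`` the cause-specific incidences and survival sum to one.
    """

    causes: list[str]
    cif: dict[str, StepFunction]
    survival: StepFunction
    n: int

    def at(self, t) -> dict[str, float]:
        out = {c: float(self.cif[c](t)) for c in self.causes}
        out["survival"] = float(self.survival(t))
        return out


def cuminc(time, cause, causes=None) -> CIFEstimate:
    """Aalen–Johansen estimator of cause-specific cumulative incidence.

    Parameters
    ----------
    time
        Follow-up times.
    cause
        Cause label per subject; the value ``"censored"`` (or ``None``/``""``)
        marks right-censoring.
    causes
        Causes to report; defaults to all observed non-censoring labels.

    Notes
    -----
    ``CIF_k(t) = Σ_{t_i ≤ t} Ŝ(t_i−) d_{k,i} / n_i`` with ``Ŝ`` the
    all-cause Kaplan–Meier estimator, so incidences and survival conserve
    probability exactly at every time point.
    """
    time = np.asarray(time, dtype=float)
    cause = np.asarray(
        ["censored" if c in (None, "", "censored") else str(c) for c in np.asarray(cause)]
    )
    if causes is None:
        causes = sorted(set(cause) - {"censored"})
    causes = [str(c) for c in causes]
    any_event = cause != "censored"

    uniq = np.unique(time[any_event])
    st = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(st, uniq, side="left")
    surv_fn = km(time, any_event)
    s_left = surv_fn.left_limit(uniq) if len(uniq) else np.array([])

    cif = {}
    for c in causes:
        tc = time[cause == c]
        d = np.zeros(len(uniq))
        if len(tc) and len(uniq):
            pos = np.searchsorted(uniq, tc)
            np.add.at(d, pos, 1)  # every cause-c time is an event time, so pos is exact
        increments = s_left * d / n_at_risk if len(uniq) else np.array([])
        cif[c] = StepFunction(x=uniq, y=np.cumsum(increments), init=0.0)
    return CIFEstimate(causes=causes, cif=cif, survival=surv_fn, n=len(time))


# ---------------------------------------------------------------------------
# incident/dynamic time-dependent AUC
# ---------------------------------------------------------------------------


class _Fenwick:
    """Binary indexed tree over marker ranks (counts + prefix sums)."""

    def __init__(self, size: int):
        self.tree = np.zeros(size + 1, dtype=np.int64)
        self.size = size

    def add(self, i: int) -> None:
        i += 1
        while i <= self.size:
            self.tree[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        # count of inserted ranks <= i
        s = 0
        i += 1
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def _incident_auc_curve(marker, time, event):
    """AUC(s) at each event time s, with case counts and control counts.

    Cases at ``s`` are subjects failing at ``s``; controls are subjects still
    at risk strictly beyond ``s``; tied markers count one half.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not np.all(np.isfinite(marker)):
        raise ValueError("marker must be finite")

    _, ranks = np.unique(marker, return_inverse=True)
    nr = ranks.max() + 1
    bit = _Fenwick(int(nr))
    order = np.argsort(-time, kind="stable")
    ev_times = np.unique(time[event])[::-1]
    cases_at: dict[float, list[int]] = {}
    for i in np.flatnonzero(event):
        cases_at.setdefault(time[i], []).append(i)

    ptr, n = 0, len(time)
    inserted = 0
    rows = []  # (s, auc, d, n_controls)
    for s in ev_times:
        while ptr < n and time[order[ptr]] > s:
            bit.add(int(ranks[order[ptr]]))
            ptr += 1
            inserted += 1
        if inserted == 0:
            continue
        case_idx = cases_at[s]
        score = 0.0
        for i in case_idx:
            r = int(ranks[i])
            less = bit.prefix(r - 1) if r > 0 else 0
            eq = bit.prefix(r) - less
            score += less + 0.5 * eq
        d = len(case_idx)
        rows.append((s, score / (d * inserted), d, inserted))
    rows.reverse()
    return rows


def td_auc(marker, time, event, horizon, mode: str = "integrated_to") -> float:
    """Incident/dynamic time-dependent AUC of a prognostic marker.

    Parameters
    ----------
    marker
        Risk score per subject (higher = higher hazard).
    time, event
        Follow-up and event indicator for the event the marker predicts.
    horizon
        Evaluation time, in the units of ``time``.
    mode
        ``"integrated_to"`` (default): concordance-weighted average of the
        incident AUC over event times up to ``horizon``, with weights
        ``2·f̂(s)·Ŝ(s)`` from the all-cause Kaplan–Meier fit — the
        Heagerty–Zheng concordance restricted to the horizon.
        ``"at_time"``: incident AUC at the event time nearest ``horizon``.

    Returns
    -------
    float in [0, 1]; 0.5 is chance-level discrimination. Invariant under
    strictly increasing transforms of the marker.
    """
    rows = [r for r in _incident_auc_curve(marker, time, event) if r[0] <= horizon]
    if not rows:
        raise ValueError(f"no usable events at or before horizon {horizon}")
    if mode == "at_time":
        s, auc, _, _ = min(rows, key=lambda r: abs(r[0] - horizon))
        return float(auc)
    if mode != "integrated_to":
        raise ValueError(f"unknown mode {mode!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    surv = km(time, event)
    weights, aucs = [], []
    for s, auc, _, _ in rows:
        f_mass = surv.left_limit(s) - surv(s)
        weights.append(2.0 * f_mass * surv(s))
        aucs.append(auc)
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        # all mass at the last event time with S=0; fall back to equal weights
        weights = np.ones_like(weights)
    return float(np.average(aucs, weights=weights))


def auc_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley–McNeil standard error of an AUC estimate.

    Used as an approximate yardstick for "better than chance by k·SE"
    checks on validation folds; it treats case/control pairs as independent,
    which is close enough for large cohorts.
    """
    if n_cases <= 0 or n_controls <= 0:
        return float("nan")
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc**2)
        + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))
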