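"""Univariate Cox proportional-hazards screening.

Feature screening fits one single-covariate Cox model per feature — often
thousands of them — so the partial-likelihood Newton iteration is written
directly on arrays and vectorised across features.  Ties are handled with
the Breslow approximation and significance is a Wald test (with a score-test
fallback when the likelihood is monotone and no finite MLE exists); features are
standardised (mean 0, sd 1) before fitting so hazard ratios are per-SD and
the iteration is numerically stable.  ``lifelines`` fits the same model and
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ITER = 50
TOL = 1e-9
_BETA_CAP = 50.0  # |beta| beyond this on a standardised covariate = divergence


@dataclass
class UnivariateCoxFit:
    coef: float
    se: float
    p: float
    converged: bool

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))


def _risk_structure(time: np.ndarray, event: np.ndarray):
    """Sort by time; return sort order, event rows and, per event row, the
    first index of its tied-time group (Breslow risk sets)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    # first index of each tied group, propagated to every member
    first = np.zeros(t.size, dtype=int)
    for i in range(1, t.size):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    ev_rows = np.flatnonzero(event[order] == 1)
    return order, ev_rows, first[ev_rows]


def univariate_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, standardize: bool = True
) -> list[UnivariateCoxFit]:
    """Fit one univariate Cox model per column of ``X``.

    Rows with NaN in a feature are dropped for that feature only.
    Degenerate features (zero variance after masking) and non-converging
    fits are reported with p = 1 rather than raising.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event must match the number of rows of X")

    results: list[UnivariateCoxFit | None] = [None] * p
    col_nan = np.isnan(X).any(axis=0)
    clean = np.flatnonzero(~col_nan)
    if clean.size:
        for j, fit in zip(clean, _batch_fit(X[:, clean], time, event, standardize)):
            results[j] = fit
    for j in np.flatnonzero(col_nan):
        mask = ~np.isnan(X[:, j])
        if mask.sum() < 3 or event[mask].sum() == 0:
            results[j] = UnivariateCoxFit(0.0, np.inf, 1.0, False)
        else:
            results[j] = _batch_fit(
                X[mask, j][:, None], time[mask], event[mask], standardize
            )[0]
    return results  # type: ignore[return-value]


def _batch_fit(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, standardize: bool
) -> list[UnivariateCoxFit]:
    n, p = X.shape
    sd = X.std(axis=0, ddof=0)
    degenerate = sd == 0
    if standardize:
        safe_sd = np.where(degenerate, 1.0, sd)
        X = (X - X.mean(axis=0)) / safe_sd

    order, ev_rows, ev_first = _risk_structure(time, event)
    Xs = X[order]
    n_events = ev_rows.size
    if n_events == 0:
        return [UnivariateCoxFit(0.0, np.inf, 1.0, False)] * p

    # score-test statistics at beta = 0: the fallback p-value for fits whose
    # partial likelihood is monotone (perfect concordance has no finite MLE)
    s0_0 = np.arange(n, 0, -1, dtype=float)[:, None]
    s1_0 = np.cumsum(Xs[::-1], axis=0)[::-1]
    s2_0 = np.cumsum((Xs * Xs)[::-1], axis=0)[::-1]
    m0 = s1_0[ev_first] / s0_0[ev_first]
    grad0 = Xs[ev_rows].sum(axis=0) - m0.sum(axis=0)
    fisher0 = np.maximum(
        (s2_0[ev_first] / s0_0[ev_first] - m0**2).sum(axis=0), 1e-12
    )
    score_p = 2 * stats.norm.sf(np.abs(grad0) / np.sqrt(fisher0))

    beta = np.zeros(p)
    active = ~degenerate
    converged = np.zeros(p, dtype=bool)
    monotone = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    last_ll = np.full(p, -np.inf)
    for _ in range(MAX_ITER):
        if not active.any():
            break
        b = beta[active]
        Xa = Xs[:, active]
        eta = np.clip(Xa * b, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum((Xa * w)[::-1], axis=0)[::-1]
        s2 = np.cumsum((Xa * Xa * w)[::-1], axis=0)[::-1]
        r0, r1, r2 = s0[ev_first], s1[ev_first], s2[ev_first]
        mean = r1 / r0
        ll = (eta[ev_rows] - np.log(r0)).sum(axis=0)
        grad = Xa[ev_rows].sum(axis=0) - mean.sum(axis=0)
        fisher = (r2 / r0 - mean**2).sum(axis=0)
        fisher = np.maximum(fisher, 1e-12)
        step = np.clip(grad / fisher, -5.0, 5.0)
        b_new = b + step
        # converge on a tiny step or a flat partial likelihood (the latter
        # terminates near-separated fits at a finite, reportable beta)
        done = (np.abs(step) < TOL) | (
            np.abs(ll - last_ll[active]) < 1e-9 * (np.abs(ll) + 1)
        )
        idx = np.flatnonzero(active)
        beta[idx] = np.where(done, b, b_new)
        info[idx] = fisher
        last_ll[idx] = ll
        converged[idx[done]] = True
        blown = np.abs(b_new) > _BETA_CAP
        monotone[idx[blown & ~done]] = True
        active_new = active.copy()
        active_new[idx[done | blown]] = False
        active = active_new

    out: list[UnivariateCoxFit] = []
    for j in range(p):
        if degenerate[j]:
            out.append(UnivariateCoxFit(0.0, np.inf, 1.0, False))
            continue
        if monotone[j]:
            # diverging beta with ever-increasing likelihood: report the
            # (always valid) score test instead of a meaningless Wald p
            out.append(UnivariateCoxFit(float(beta[j]), np.inf, float(score_p[j]), True))
            continue
        ok = bool(converged[j]) and np.isfinite(info[j]) and abs(beta[j]) <= _BETA_CAP
        if not ok:
            out.append(UnivariateCoxFit(float(beta[j]), np.inf, 1.0, False))
            continue
        se = float(1.0 / np.sqrt(info[j]))
        z = beta[j] / se
        pval = float(2 * stats.norm.sf(abs(z)))
        out.append(UnivariateCoxFit(float(beta[j]), se, pval, True))
    return out
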