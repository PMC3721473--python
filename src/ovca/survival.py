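"""Survival curves and tests, Cox PH regression, rank statistics and GI50.

Kaplan-Meier, the k-group log-rank test and the Breslow-ties Cox partial
likelihood are implemented directly (tests carry hand-computed oracles and
lifelines cross-checks); Fisher's exact test and the Mann-Whitney U test
are delegated to scipy, whose conventions (probability-mass two-sided rule,
exact small-sample enumeration) match the contracts here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "fisher_exact",
    "mann_whitney_u",
    "spearman_matrix",
    "gi50",
]


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) != len(event):
        raise ValueError("time and event lengths differ")
    if np.any(time <= 0):
        raise ValueError("survival times must be > 0")
    if set(np.unique(event)) - {0, 1}:
        raise ValueError("event indicators must be 0/1")
    return time, event


def km_estimate(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns a mapping group -> DataFrame(time, n_at_risk, n_events,
    survival); S(0) = 1 and S is non-increasing. With ``groups=None`` a
    single group ``"all"`` is used.
    """
    time, event = _check_surv(time, event)
    if groups is None:
        groups = np.full(len(time), "all", dtype=object)
    groups = np.asarray(groups, dtype=object)
    out: dict[str, pd.DataFrame] = {}
    for g in sorted(set(map(str, groups))):
        mask = groups.astype(str) == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        t, e = time[mask], event[mask]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t[e == 1])
        rows = [{"time": 0.0, "n_at_risk": len(t), "n_events": 0, "survival": 1.0}]
        s = 1.0
        for u in uniq:
            at_risk = int(np.sum(t >= u))
            d = int(np.sum((t == u) & (e == 1)))
            s *= 1.0 - d / at_risk
            rows.append({"time": float(u), "n_at_risk": at_risk, "n_events": d, "survival": s})
        out[g] = pd.DataFrame(rows)
    return out


def logrank_test(time, event, groups):
    """k-group log-rank test: observed minus expected over hypergeometric variance.

    Returns ``(chi2, df, p)``. For two groups chi2 equals the squared
    standardized O - E of either group.
    """
    time, event = _check_surv(time, event)
    groups = np.asarray(groups, dtype=object).astype(str)
    levels = sorted(set(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if event.sum() < 1:
        raise ValueError("log-rank needs >= 1 event")
    G = np.column_stack([(groups == g).astype(float) for g in levels])  # n x k
    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = time >= u
        n = at_risk.sum()
        d = float(np.sum((time == u) & (event == 1)))
        n_g = G[at_risk].sum(axis=0)
        d_g = G[(time == u) & (event == 1)].sum(axis=0)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vr) @ z)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Cox proportional-hazards fit via Newton-Raphson on the Breslow partial likelihood.

    Returns a DataFrame indexed by covariate with columns coef, hr, se,
    ci_low, ci_high, p (Wald). Errors on constant covariates,
    non-convergence, and warns on monotone likelihood (complete separation).
    """
    time, event = _check_surv(time, event)
    X = np.asarray(covariates, dtype=float)
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    for j in range(p):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"covariate {names[j]!r} is constant")
    if event.sum() < p:
        raise ValueError("fewer events than covariates")

    # center covariates for numerical stability (does not change beta)
    center = X.mean(axis=0)
    Xc = X - center

    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], Xc[order]
    n_s = len(t_s)
    # first index of each tie group: Breslow risk-set sums start there
    first_of_tie = np.zeros(n_s, dtype=np.int64)
    for i in range(1, n_s):
        first_of_tie[i] = first_of_tie[i - 1] if t_s[i] == t_s[i - 1] else i
    ev_idx = np.where(e_s == 1)[0]
    ev_start = first_of_tie[ev_idx]
    # pairwise products x_j x_k flattened for the suffix-summed S2
    Xpair = (X_s[:, :, None] * X_s[:, None, :]).reshape(n_s, p * p)

    def _grad_hess(beta):
        w = np.exp(X_s @ beta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
        s2 = np.cumsum((w[:, None] * Xpair)[::-1], axis=0)[::-1]
        r0 = s0[ev_start][:, None]
        r1 = s1[ev_start]
        r2 = s2[ev_start].reshape(-1, p, p)
        mean = r1 / r0
        grad = (X_s[ev_idx] - mean).sum(axis=0)
        info = (r2 / r0[:, :, None] - mean[:, :, None] * mean[:, None, :]).sum(axis=0)
        return grad, info

    beta = np.zeros(p)
    for it in range(max_iter):
        grad, info = _grad_hess(beta)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix in Cox fit") from err
        beta_new = beta + step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
        if np.max(np.abs(beta)) > 50:
            warnings.warn(
                "monotone partial likelihood (possible complete separation)", stacklevel=2
            )
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )

    _, info = _grad_hess(beta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=names,
    )


def fisher_exact(table):
    """Two-sided Fisher exact p (probability-mass rule) and sample odds ratio."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    a, b, c, d = t.ravel()
    res = stats.fisher_exact(t, alternative="two-sided")
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = np.nan
    return float(res.pvalue), float(odds)


def mann_whitney_u(x, y, exact_below: int = 20):
    """Mann-Whitney U with exact small-sample p, normal approximation otherwise.

    Exact enumeration applies when both samples are smaller than
    ``exact_below`` and tie-free; otherwise the tie-corrected normal
    approximation (without continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) < exact_below and len(y) < exact_below and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(A, B=None):
    """Spearman rho (+ p) between the columns of A and B (midrank ties).

    Returns ``(rho DataFrame, p DataFrame)``; constant columns produce NaN
    with a warning.
    """
    A = pd.DataFrame(A)
    B = A if B is None else pd.DataFrame(B)
    if len(A) != len(B):
        raise ValueError("A and B need the same number of rows")
    if len(A) < 3:
        raise ValueError("spearman needs >= 3 paired observations")
    rho = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    pval = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    warned = False
    for ca in A.columns:
        for cb in B.columns:
            xa, xb = A[ca].to_numpy(), B[cb].to_numpy()
            if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                if not warned:
                    warnings.warn("constant column(s): rho undefined, reported NaN", stacklevel=2)
                    warned = True
                rho.loc[ca, cb] = np.nan
                pval.loc[ca, cb] = np.nan
                continue
            r, p = stats.spearmanr(xa, xb)
            rho.loc[ca, cb] = r
            pval.loc[ca, cb] = p
    return rho, pval


def _four_pl(logc, bottom, top, log_gi50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_gi50)))


def gi50(concentrations, viability, model: str = "fourPL"):
    """GI50 from a dilution-series viability curve.

    ``fourPL`` fits a four-parameter logistic on log-concentration and
    returns the concentration where the fitted curve crosses 50%;
    ``loglinear-interp`` interpolates linearly in log-dose between the
    bracketing observations. If viability never falls below 50% the result
    is right-censored: ``(nan, "> max dose")``. Returns ``(gi50, status)``
    with status ``"ok"`` when estimated.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viability, dtype=float)
    if len(conc) < 4:
        raise ValueError("gi50 needs >= 4 concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, viab = conc[order], viab[order]
    diffs = np.diff(viab)
    if np.any(diffs > 10.0):
        warnings.warn("non-monotone dose-response beyond tolerance", stacklevel=2)
    if np.all(viab > 50.0):
        return float("nan"), "> max dose"
    if np.all(viab < 50.0):
        return float("nan"), "< min dose"

    logc = np.log10(conc)

    def interp():
        below = np.where(viab <= 50.0)[0][0]
        above = below - 1
        if above < 0:
            return float(conc[below])
        x0, x1 = logc[above], logc[below]
        y0, y1 = viab[above], viab[below]
        xm = x0 + (50.0 - y0) * (x1 - x0) / (y1 - y0)
        return float(10**xm)

    if model == "loglinear-interp":
        return interp(), "ok"
    if model != "fourPL":
        raise ValueError(f"unknown model {model!r}")
    try:
        p0 = [float(viab.min()), float(viab.max()), float(np.median(logc)), 1.0]
        popt, _ = curve_fit(_four_pl, logc, viab, p0=p0, maxfev=10000)
        bottom, top, log_gi50, hill = popt
        # concentration where the fitted curve equals 50
        if not (min(bottom, top) < 50.0 < max(bottom, top)):
            return interp(), "ok"
        frac = (top - bottom) / (50.0 - bottom) - 1.0
        if frac <= 0 or hill == 0:
            return interp(), "ok"
        x50 = log_gi50 + np.log(frac) / hill
        if not np.isfinite(x50):
            return interp(), "ok"
        return float(10**x50), "ok"
    except RuntimeError:
        return interp(), "ok"
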