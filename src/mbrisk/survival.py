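"""Survival and categorical statistics implemented from first principles.

Provides the estimators the cross-trial analysis relies on:

* Kaplan-Meier product-limit curves with Greenwood standard errors,
* the k-sample log-rank test with hypergeometric variance,
* Cox proportional-hazards regression with Efron tie correction,
  Newton-Raphson maximisation, and monotone-likelihood (separation)
  detection,
* Harrell's concordance index for censored data,
* bootstrap comparison of two risk scores by concordance difference,
* the exact two-sided Fisher test for 2x2 tables
  (probability-mass rule, computed with exact rational arithmetic).

Conventions, stated because month-resolution trial data are heavily
tied: censored subjects at an event time remain at risk for that event
time (events precede censorings at ties); Efron's approximation, not
Breslow's, handles tied event times in the partial likelihood; all
tests are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalSample:
    """Right-censored follow-up: times in months, event indicator 0/1,
    optional covariate matrix (subjects x terms)."""

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be equal-length 1-D arrays")
        if self.time.size and np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if self.time.size and not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        if self.covariates is not None:
            X = np.asarray(self.covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if X.shape[0] != self.time.size:
                raise ValueError("covariate rows must match number of subjects")
            self.covariates = X

    def __len__(self) -> int:
        return self.time.size

    def subset(self, idx) -> "SurvivalSample":
        X = None if self.covariates is None else self.covariates[idx]
        return SurvivalSample(self.time[idx], self.event[idx], X)


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    time: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    std_err: np.ndarray

    def survival_at(self, t: float) -> float:
        return survival_at(self, t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "se": self.std_err,
            }
        )


def km_estimate(sample: SurvivalSample) -> SurvivalCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i) with
    Greenwood variance S(t)^2 sum d_i / (n_i (n_i - d_i))."""
    if len(sample) == 0:
        raise ValueError("cannot estimate a survival curve from an empty sample")
    t, e = sample.time, sample.event
    event_times = np.unique(t[e == 1])
    n_risk, n_event, surv, se = [], [], [], []
    s = 1.0
    greenwood = 0.0
    for ti in event_times:
        ni = int(np.sum(t >= ti))
        di = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - di / ni
        if ni > di:
            greenwood += di / (ni * (ni - di))
            se_i = s * math.sqrt(greenwood)
        else:
            se_i = 0.0  # curve has reached zero
        n_risk.append(ni)
        n_event.append(di)
        surv.append(s)
        se.append(se_i)
    return SurvivalCurve(
        time=np.asarray(event_times, dtype=float),
        n_risk=np.asarray(n_risk, dtype=int),
        n_event=np.asarray(n_event, dtype=int),
        survival=np.asarray(surv, dtype=float),
        std_err=np.asarray(se, dtype=float),
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step-function evaluation of the curve at ``t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    i = int(np.searchsorted(curve.time, t, side="right")) - 1
    return 1.0 if i < 0 else float(curve.survival[i])


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(groups: list[SurvivalSample]) -> LogrankResult:
    """k-sample log-rank test: O - E over pooled event times with the
    hypergeometric variance; chi-square on k - 1 degrees of freedom."""
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("log-rank test groups must be non-empty")
    time = np.concatenate([g.time for g in groups])
    event = np.concatenate([g.event for g in groups])
    gidx = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for ti in event_times:
        at_risk = time >= ti
        n_j = int(at_risk.sum())
        dying = (time == ti) & (event == 1)
        d_j = int(dying.sum())
        n_ij = np.array([(at_risk & (gidx == i)).sum() for i in range(k)], dtype=float)
        d_ij = np.array([(dying & (gidx == i)).sum() for i in range(k)], dtype=float)
        O += d_ij
        E += d_j * n_ij / n_j
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1)
            V += c * (np.diag(n_ij) / n_j - np.outer(n_ij, n_ij) / n_j**2)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z) if z.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p_value=p, observed=O, expected=E)


@dataclass
class CoxResult:
    beta: np.ndarray
    std_err: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_wald: np.ndarray
    loglik: float
    score_chi2: float
    score_p: float
    n_iter: int
    converged: bool
    separation: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se(coef)": self.std_err,
                "HR": self.hazard_ratio,
                "HR 95% lower": self.ci_lower,
                "HR 95% upper": self.ci_upper,
                "p": self.p_wald,
            }
        )


def _efron_quantities(t, e, X, beta):
    """Log partial likelihood, gradient and information with Efron ties.

    Assumes rows sorted ascending by time.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    r = np.exp(eta)
    rx = r[:, None] * X
    rxx = r[:, None, None] * (X[:, :, None] * X[:, None, :])
    # suffix sums: S*[i] aggregates subjects i..n-1
    S0 = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    S1 = np.concatenate([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, p))])
    S2 = np.concatenate(
        [np.cumsum(rxx[::-1], axis=0)[::-1], np.zeros((1, p, p))]
    )
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for ti in np.unique(t[e == 1]):
        first = int(np.searchsorted(t, ti, side="left"))
        D = np.where((t == ti) & (e == 1))[0]
        d = D.size
        sR0, sR1, sR2 = S0[first], S1[first], S2[first]
        sD0 = r[D].sum()
        sD1 = rx[D].sum(axis=0)
        sD2 = rxx[D].sum(axis=0)
        ll += float(eta[D].sum())
        grad += X[D].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = sR0 - f * sD0
            Z = sR1 - f * sD1
            W = sR2 - f * sD2
            ll -= math.log(phi)
            grad -= Z / phi
            info += W / phi - np.outer(Z, Z) / phi**2
    return ll, grad, info


def cox_fit(
    sample: SurvivalSample,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Convergence: relative log-partial-likelihood change below ``tol`` or
    ``max_iter`` iterations.  Monotone likelihood (separation) is
    detected from diverging coefficients and flagged, never silently
    returned as a converged estimate.
    """
    if sample.covariates is None:
        raise ValueError("cox_fit requires covariates")
    if sample.event.sum() < 1:
        raise ValueError("cox_fit requires at least one event")
    X = sample.covariates
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate detected")
    order = np.argsort(sample.time, kind="mergesort")
    t, e = sample.time[order], sample.event[order]
    means = X.mean(axis=0)
    Xc = X[order] - means  # centered for numerical stability
    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(t, e, Xc, beta)
    score_chi2 = float(grad @ np.linalg.solve(info, grad))
    score_p = float(stats.chi2.sf(score_chi2, p))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = np.linalg.solve(info, grad)
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_quantities(t, e, Xc, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_quantities(t, e, Xc, new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if rel_change < tol:
            converged = True
            break
    separation = bool(np.max(np.abs(beta)) > 10.0)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # separated fits have huge CIs
        return CoxResult(
            beta=beta,
            std_err=se,
            hazard_ratio=np.exp(beta),
            ci_lower=np.exp(beta - zcrit * se),
            ci_upper=np.exp(beta + zcrit * se),
            p_wald=2.0 * stats.norm.sf(np.abs(z)),
            loglik=ll,
            score_chi2=score_chi2,
            score_p=score_p,
            n_iter=n_iter,
            converged=converged,
            separation=separation,
        )


def concordance_index(risk_scores, sample: SurvivalSample) -> float:
    """Harrell's c over usable pairs.

    A pair is usable iff the member with the shorter observed time had
    an event (equal observed times: event vs censored counts, with the
    event member failing first; two tied events are not orderable).
    Higher scores must predict shorter survival; tied scores count 1/2.
    """
    s = np.asarray(risk_scores, dtype=float)
    if s.shape != sample.time.shape:
        raise ValueError("risk scores must align with subjects")
    t, e = sample.time, sample.event
    num = 0.0
    den = 0
    for i in np.where(e == 1)[0]:
        comparable = (t > t[i]) | ((t == t[i]) & (e == 0))
        comparable[i] = False
        m = int(comparable.sum())
        if m == 0:
            continue
        den += m
        num += float(np.sum(s[i] > s[comparable]))
        num += 0.5 * float(np.sum(s[i] == s[comparable]))
    if den == 0:
        raise ValueError("no usable pairs for concordance")
    return num / den


@dataclass
class BootstrapComparison:
    mean_diff: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    n_skipped: int
    diffs: np.ndarray = field(repr=False)


def bootstrap_compare(
    scores_a,
    scores_b,
    sample: SurvivalSample,
    n_boot: int = 500,
    seed: int | None = None,
) -> BootstrapComparison:
    """Bootstrap distribution of the c-index difference c(A) - c(B).

    Subjects are resampled with replacement; degenerate resamples (no
    events / no usable pairs) are skipped and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    n = len(sample)
    if a.shape != (n,) or b.shape != (n,):
        raise ValueError("score vectors must align with subjects")
    rng = np.random.default_rng(seed)
    diffs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = sample.subset(idx)
        if sub.event.sum() == 0:
            skipped += 1
            continue
        try:
            ca = concordance_index(a[idx], sub)
            cb = concordance_index(b[idx], sub)
        except ValueError:
            skipped += 1
            continue
        diffs.append(ca - cb)
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapComparison(
        mean_diff=float(diffs.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_boot=n_boot,
        n_skipped=skipped,
        diffs=diffs,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by the probability-mass
    rule: the sum of hypergeometric probabilities of all tables with the
    same margins that are no more probable than the observed one."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, c1, c2 = a + b, a + c, b + d
    n = a + b + c + d
    if min(r1, c + d, c1, c2) <= 0:
        raise ValueError("all margins must be positive")
    denom = math.comb(n, r1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(c1, x) * math.comb(c2, r1 - x), denom)

    p_obs = prob(a)
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    total = sum((px for x in range(lo, hi + 1) if (px := prob(x)) <= p_obs), Fraction(0))
    return float(total)
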