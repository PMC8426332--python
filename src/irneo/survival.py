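"""Survival association of neoantigen load, implemented from first principles.

Load is dichotomised at the cohort median (high = strictly above; ties go
low). Group comparison uses the Kaplan-Meier product-limit estimator and the
two-group log-rank test; adjusted effects come from a Cox proportional-
hazards model fit by Newton-Raphson on the partial likelihood with the
Breslow approximation for tied event times (Efron available by flag). The
Spearman rank correlation (average ranks for ties, t-approximation p-value)
quantifies the event-count/load relation.

scipy supplies only distribution tails; the estimators themselves live here
so their numerics (tie conventions, convergence rules) are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .neoantigen import SampleLoad


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: int  # 1 = death, 0 = censored
    covariates: dict[str, float | str] = field(default_factory=dict)
    load_group: Optional[str] = None  # "high" / "low"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class CoxFit:
    """Cox PH estimates: per covariate (beta, HR, se, Wald p, 95% CI)."""

    coefficients: dict[str, dict[str, float]]
    n: int
    n_events: int
    converged: bool
    loglik: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients).T[
            ["beta", "hazard_ratio", "se", "wald_p", "ci95_low", "ci95_high"]
        ]


def dichotomize_load(
    loads: Sequence[SampleLoad], field_name: str = "neoag_load"
) -> dict[str, str]:
    """Median split: high iff value strictly above the cohort median."""
    if field_name not in ("neoag_load", "weighted_load"):
        raise ValueError("field must be neoag_load or weighted_load")
    if len(loads) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    values = np.array([getattr(s, field_name) for s in loads], dtype=float)
    if np.all(values == values[0]):
        raise ValueError("degenerate split: all load values identical")
    med = float(np.median(values))
    return {s.sample_id: ("high" if getattr(s, field_name) > med else "low") for s in loads}


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit estimator; at tied times deaths precede censorings.

    Returns one row per distinct event time: time, n_at_risk, n_events,
    survival.
    """
    if not records:
        raise ValueError("need >= 1 record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    rows = []
    s = 1.0
    n = len(times)
    at_risk = n
    for t in np.unique(times):
        here = times == t
        d = int(events[here].sum())
        c = int((~events[here].astype(bool)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((float(t), at_risk, d, s))
        at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _two_group_arrays(group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]):
    t = np.array([r.time for r in group_a] + [r.time for r in group_b])
    e = np.array([r.event for r in group_a] + [r.event for r in group_b])
    g = np.array([0] * len(group_a) + [1] * len(group_b))
    return t, e, g


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: ((O - E)^2 / V, chi-square upper-tail p, 1 df)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    t, e, g = _two_group_arrays(group_a, group_b)
    if e.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    stat = _logrank_statistic(t, e, g)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def _logrank_statistic(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> float:
    o_minus_e = 0.0
    var = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & (g == 1)).sum())
        d_j = int(((t == tj) & (e == 1)).sum())
        d1_j = int(((t == tj) & (e == 1) & (g == 1)).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def _design_matrix(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Numeric covariates pass through; string-valued covariates are one-hot
    encoded against a declared (or lexicographically first) reference level;
    load_group maps high=1/low=0."""
    reference_levels = dict(reference_levels or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "load_group":
            vals = [1.0 if r.load_group == "high" else 0.0 for r in records]
            cols.append(np.array(vals))
            names.append("load_group[high]")
            continue
        raw = [r.covariates[cov] for r in records]
        if all(isinstance(v, (int, float, np.integer, np.floating)) for v in raw):
            cols.append(np.array(raw, dtype=float))
            names.append(cov)
        else:
            levels = sorted({str(v) for v in raw})
            ref = reference_levels.get(cov, levels[0])
            for lvl in levels:
                if lvl == ref:
                    continue
                cols.append(np.array([1.0 if str(v) == lvl else 0.0 for v in raw]))
                names.append(f"{cov}[{lvl}]")
    x = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return x, names


def _partial_loglik(beta, x, times, events, ties="breslow"):
    """Breslow/Efron partial log-likelihood with gradient and information."""
    n, p = x.shape
    eta = x @ beta
    order = np.argsort(-times, kind="stable")  # decreasing time
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        # absorb everyone entering the risk set at this time
        j = i
        while j < n and times[order[j]] == t:
            idx = order[j]
            w = np.exp(eta[idx])
            s0 += w
            s1 += w * x[idx]
            s2 += w * np.outer(x[idx], x[idx])
            j += 1
        dead = [order[k] for k in range(i, j) if events[order[k]] == 1]
        d = len(dead)
        if d > 0:
            xd = x[dead]
            if ties == "breslow":
                ll += eta[dead].sum() - d * np.log(s0)
                mean = s1 / s0
                grad += xd.sum(axis=0) - d * mean
                info += d * (s2 / s0 - np.outer(mean, mean))
            else:  # efron
                wd = np.exp(eta[dead])
                s0d = wd.sum()
                s1d = (wd[:, None] * xd).sum(axis=0)
                s2d = np.einsum("i,ij,ik->jk", wd, xd, xd)
                ll += eta[dead].sum()
                grad += xd.sum(axis=0)
                for m in range(d):
                    f = m / d
                    denom = s0 - f * s0d
                    num1 = s1 - f * s1d
                    num2 = s2 - f * s2d
                    ll -= np.log(denom)
                    mean = num1 / denom
                    grad -= mean
                    info += num2 / denom - np.outer(mean, mean)
        i = j
    return ll, grad, info


def cox_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    ties: str = "breslow",
    reference_levels: Mapping[str, str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson on the partial likelihood.

    Convergence when the max absolute score component drops below tol (1e-8)
    within max_iter (50) iterations; Wald SEs from the observed information.
    Non-convergence or a singular information matrix is reported via
    converged=False (complete separation typically presents as both).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    x, names = _design_matrix(records, covariates, reference_levels)
    n, p = x.shape
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    n_events = int(events.sum())
    if p == 0:
        raise ValueError("no covariates to fit")
    for k in range(p):
        if np.unique(x[:, k]).size < 2:
            raise ValueError(f"covariate {names[k]} is constant")
    if n_events < p:
        raise ValueError("fewer events than model terms")

    beta = np.zeros(p)
    converged = False
    ll_prev = -np.inf
    ll = ll_prev
    for _ in range(max_iter):
        ll, grad, info = _partial_loglik(beta, x, times, events, ties)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood ascending
        for _h in range(30):
            cand = beta + step
            ll_cand, _, _ = _partial_loglik(cand, x, times, events, ties)
            if ll_cand >= ll or np.isclose(ll_cand, ll):
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(beta)) > 50:
            break  # runaway coefficients: separation
        ll_prev = ll

    ll, grad, info = _partial_loglik(beta, x, times, events, ties)
    if np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    coeffs = {}
    for k, name in enumerate(names):
        b, s = float(beta[k]), float(se[k])
        z = b / s if s > 0 else np.nan
        coeffs[name] = {
            "beta": b,
            "hazard_ratio": float(np.exp(b)),
            "se": s,
            "wald_p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            "ci95_low": float(np.exp(b - 1.96 * s)),
            "ci95_high": float(np.exp(b + 1.96 * s)),
        }
    return CoxFit(coefficients=coeffs, n=n, n_events=n_events, converged=converged, loglik=float(ll))


def cox_score_test(records: Sequence[SurvivalRecord], covariates: Sequence[str]) -> float:
    """Score (Rao) test statistic at beta = 0; for one binary covariate with
    Breslow ties this equals the log-rank chi-square."""
    x, _ = _design_matrix(records, covariates)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    _, grad, info = _partial_loglik(np.zeros(x.shape[1]), x, times, events, "breslow")
    return float(grad @ np.linalg.solve(info, grad))


def _average_ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[order[j]] == v[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average of ranks i+1..j
        i = j
    return ranks


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p-value from the
    t approximation with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    n = len(x)
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def read_clinical_table(path) -> list[SurvivalRecord]:
    """Clinical TSV: sample_id, os_months, os_event, plus covariate columns."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "os_months", "os_event"}
    if not needed <= set(df.columns):
        raise ValueError(f"clinical table {path} needs columns {sorted(needed)}")
    cov_cols = [c for c in df.columns if c not in needed]
    out = []
    for row in df.itertuples(index=False):
        covs = {c: getattr(row, c) for c in cov_cols}
        out.append(
            SurvivalRecord(
                sample_id=str(row.sample_id),
                time=float(row.os_months),
                event=int(row.os_event),
                covariates=covs,
            )
        )
    return out
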