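"""Median-split Kaplan–Meier analysis, log-rank test and Mantel–Haenszel HR.

Subjects are split into low/high cohorts at the median expression of the
queried gene (ties go to low, matching a 50:50 percentile split on distinct
values). The Kaplan–Meier product-limit curves come from lifelines; the
log-rank statistic and the Mantel–Haenszel hazard ratio are computed from the
shared observed/expected event table:

    HR = (O_high / E_high) / (O_low / E_low),
    Var(log HR) ~= 1/E_high + 1/E_low,  CI = exp(log HR +/- 1.96 * SE).

The univariate Mantel–Haenszel estimator is used instead of a Cox fit; the
two can diverge in small samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

log = logging.getLogger("coexffl.survival")


def median_split(table: pd.DataFrame, gene: str) -> pd.Series:
    """Cohort labels: "high" where expression strictly exceeds the median.

    Ties go to the low cohort. Raises when the gene column is missing, has
    fewer than 4 usable subjects, or no split is possible (all values equal).
    """
    if gene not in table.columns:
        raise KeyError(f"gene {gene!r} not in survival table")
    expr = pd.to_numeric(table[gene], errors="coerce")
    ok = expr.notna()
    if ok.sum() < 4:
        raise ValueError("need at least 4 subjects with expression values")
    med = expr[ok].median()
    if expr[ok].nunique() == 1:
        raise ValueError("all expression values equal; no median split possible")
    labels = pd.Series(np.where(expr > med, "high", "low"), index=table.index)
    labels[~ok] = pd.NA
    return labels


@dataclass
class KMCurve:
    curve: pd.DataFrame  # time, survival
    median: float  # NaN when S never reaches 0.5

    @property
    def median_defined(self) -> bool:
        return not math.isnan(self.median)


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit survival curve and median survival time.

    At tied times deaths are processed before censorings (the standard
    convention). The median is the smallest time with S(t) <= 0.5 and is
    undefined (NaN, flagged) when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        log.warning("no events: survival curve is flat, median undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    med = float(kmf.median_survival_time_)  # inf when S never reaches 0.5
    return KMCurve(curve=curve, median=(med if np.isfinite(med) else float("nan")))


def _risk_table(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Observed/expected events per group and hypergeometric variance.

    Returns (O1, E1, O0, E0, V) where group 1 is ``groups == 1``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    o1 = e1 = o0 = e0 = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & (groups == 1)).sum()
        o1 += d1
        o0 += d - d1
        e1 += d * n1 / n
        e0 += d * (n - n1) / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1, o0, e0, var


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    groups = np.asarray(groups)
    if len(set(groups.tolist())) != 2:
        raise ValueError("log-rank test needs exactly two non-empty cohorts")
    if np.asarray(events).sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    gvals = sorted(set(groups.tolist()))
    g = (groups == gvals[1]).astype(int)
    o1, e1, _, _, var = _risk_table(times, events, g)
    if var == 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Mantel–Haenszel hazard ratio of group 1 vs group 0 with 95% CI."""
    groups = np.asarray(groups, dtype=int)
    ev = np.asarray(events, dtype=int)
    for gval in (0, 1):
        if ev[groups == gval].sum() < 1:
            raise ValueError("both cohorts need at least one event")
    o1, e1, o0, e0, _ = _risk_table(times, events, groups)
    if e1 == 0 or e0 == 0:
        raise ValueError("zero expected events in a cohort")
    hr = (o1 / e1) / (o0 / e0)
    se = math.sqrt(1.0 / e1 + 1.0 / e0)
    lo, hi = hr * math.exp(-1.96 * se), hr * math.exp(1.96 * se)
    return float(hr), (float(lo), float(hi))


@dataclass
class KMResult:
    gene: str
    curves: dict[str, KMCurve]  # "low"/"high"
    medians: dict[str, float]
    chi2: float
    p: float
    hr: float
    ci: tuple[float, float]
    n: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_low": self.n["low"],
            "n_high": self.n["high"],
            "median_low": self.medians["low"],
            "median_high": self.medians["high"],
            "logrank_chi2": self.chi2,
            "logrank_p": self.p,
            "hr": self.hr,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
        }


def analyze_gene(table: pd.DataFrame, gene: str) -> KMResult:
    """Median-split KM analysis of one gene: curves, log-rank, MH hazard ratio."""
    labels = median_split(table, gene)
    ok = labels.notna()
    sub = table[ok]
    lab = labels[ok]
    times = sub["time_months"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    groups = (lab == "high").to_numpy(dtype=int)
    curves = {}
    medians = {}
    for name, mask in (("low", groups == 0), ("high", groups == 1)):
        km = km_estimate(times[mask], events[mask])
        curves[name] = km
        medians[name] = km.median
    chi2, p = logrank_test(times, events, groups)
    hr, ci = hazard_ratio(times, events, groups)
    return KMResult(
        gene=gene,
        curves=curves,
        medians=medians,
        chi2=chi2,
        p=p,
        hr=hr,
        ci=ci,
        n={"low": int((groups == 0).sum()), "high": int((groups == 1).sum())},
    )
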