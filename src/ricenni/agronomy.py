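"""Critical nitrogen dilution curve construction and nitrogen nutrition index (NNI).

The critical nitrogen concentration Nc is the minimum plant N concentration (in
percent of dry matter) needed to reach maximum aboveground biomass (AGB, t/hm²)
at a given biomass level. Across a growth period it follows a declining power
law ("dilution curve"),

    Nc(DM) = a * DM**(-b),        a > 0, b > 0,

and the nitrogen nutrition index is the ratio of the measured N concentration
to the critical one at the plant's current biomass,

    NNI = Nnc / Nc(AGB),

with NNI < 1 indicating deficit and NNI >= 1 a nitrogen-rich status.

The curve is built by the classical five-step procedure: per sampling day,
(1) split fertilization gradients into N-limited and non-limited groups by
analysis of variance on AGB, (2) fit a line of N concentration on AGB over the
limited samples, (3) take the mean AGB of the non-limited samples as the day's
maximum AGB, (4) evaluate the line there to obtain the day's critical point,
and (5) fit the power law through the per-day critical points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "KjeldahlSample",
    "DayPartition",
    "CriticalPoint",
    "CriticalCurve",
    "NniRecord",
    "DegenerateFitError",
    "kjeldahl_n_concentration",
    "partition_n_limited",
    "critical_point_for_day",
    "fit_critical_curve",
    "compute_nni",
    "compute_nni_table",
    "classify_nni",
]


class DegenerateFitError(ValueError):
    """Raised when a regression step has no usable spread in its inputs."""


@dataclass(frozen=True)
class KjeldahlSample:
    """One Kjeldahl titration: acid volume ``v_ml`` (mL) and dry mass ``m_g`` (g)."""

    v_ml: float
    m_g: float


@dataclass(frozen=True)
class DayPartition:
    """Gradient labels split into N-limited and non-limited groups for one day."""

    day: object
    limited: frozenset
    non_limited: frozenset

    def __post_init__(self) -> None:
        if self.limited & self.non_limited:
            raise ValueError("limited and non-limited groups overlap")
        if not self.non_limited:
            raise ValueError("non-limited group must be non-empty")


@dataclass(frozen=True)
class CriticalPoint:
    """Per-day critical point: maximum AGB and the critical N concentration there."""

    day: object
    agb_max: float
    n_critical: float

    def __post_init__(self) -> None:
        if self.agb_max <= 0 or self.n_critical <= 0:
            raise ValueError("critical point coordinates must be positive")


@dataclass(frozen=True)
class CriticalCurve:
    """Fitted dilution curve Nc = a * DM**(-b) with fit diagnostics."""

    a: float
    b: float
    r2: float = float("nan")
    rmse: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("curve parameters a and b must be positive")

    def critical_n(self, agb) -> np.ndarray | float:
        """Evaluate Nc(AGB) in percent for AGB in t/hm²."""
        agb = np.asarray(agb, dtype=float)
        if np.any(agb <= 0):
            raise ValueError("AGB must be positive")
        out = self.a * agb ** (-self.b)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class NniRecord:
    sample_id: object
    nni: float
    group: str = field(default="")

    def __post_init__(self) -> None:
        if self.nni <= 0:
            raise ValueError("NNI must be positive")
        expected = classify_nni(self.nni)
        if self.group and self.group != expected:
            raise ValueError(f"group {self.group!r} inconsistent with nni={self.nni}")
        if not self.group:
            object.__setattr__(self, "group", expected)


def kjeldahl_n_concentration(sample: KjeldahlSample) -> float:
    """Plant N concentration (%) from a Kjeldahl titration.

    N% = V * 0.05 * 0.014 / M * 100, with V the 0.05 mol/L hydrochloric acid
    volume in mL (0.014 g N per mmol of acid) and M the dry sample mass in g.
    """
    if sample.m_g <= 0:
        raise ValueError("sample mass must be positive")
    if sample.v_ml < 0:
        raise ValueError("titration volume cannot be negative")
    return sample.v_ml * 0.05 * 0.014 / sample.m_g * 100.0


def classify_nni(nni: float) -> str:
    """Classify an NNI value: ``deficit`` if NNI < 1, ``rich`` if NNI >= 1."""
    if nni <= 0:
        raise ValueError("NNI must be positive")
    return "deficit" if nni < 1.0 else "rich"


def _group_arrays(day_samples: pd.DataFrame) -> dict:
    groups = {}
    for label, sub in day_samples.groupby("gradient", sort=True):
        groups[label] = np.asarray(sub["agb_t_hm2"], dtype=float)
    return groups


def partition_n_limited(day_samples: pd.DataFrame, alpha: float = 0.05,
                        mean_tolerance: float = 0.05) -> DayPartition:
    """Split one day's fertilization gradients into N-limited / non-limited groups.

    With replicated plots the split uses a one-way ANOVA on AGB across gradients
    followed by Tukey HSD comparisons of each gradient against the gradient with
    the highest mean AGB: gradients significantly *lower* than the top one are
    N-limited, the rest (including the top) are non-limited. If the overall
    ANOVA finds no differences at level ``alpha`` every gradient is non-limited.

    Without replicates (any gradient has a single observation) a means-only
    rule is used: a gradient is non-limited when its mean AGB is at least
    ``(1 - mean_tolerance)`` times the maximum gradient mean.

    Parameters
    ----------
    day_samples : DataFrame with columns ``gradient`` and ``agb_t_hm2`` for a
        single sampling day.
    alpha : significance level of the ANOVA / Tukey comparisons.
    mean_tolerance : relative tolerance of the no-replicate fallback.
    """
    groups = _group_arrays(day_samples)
    if len(groups) < 2:
        raise ValueError("at least 2 fertilization gradients are required")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every gradient needs at least one observation")
    day = day_samples["day"].iloc[0] if "day" in day_samples else None
    labels = list(groups)
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    top = max(labels, key=lambda g: means[g])

    if any(len(v) < 2 for v in groups.values()):
        thresh = (1.0 - mean_tolerance) * means[top]
        non_limited = frozenset(g for g in labels if means[g] >= thresh)
        return DayPartition(day, frozenset(set(labels) - non_limited), non_limited)

    pooled_var = np.mean([np.var(v, ddof=1) for v in groups.values()])
    if pooled_var == 0.0:
        # Degenerate replicates: any mean difference is "significant".
        non_limited = frozenset(g for g in labels if means[g] == means[top])
        return DayPartition(day, frozenset(set(labels) - non_limited), non_limited)

    _, p_anova = stats.f_oneway(*groups.values())
    if p_anova >= alpha:
        return DayPartition(day, frozenset(), frozenset(labels))

    res = stats.tukey_hsd(*[groups[g] for g in labels])
    top_idx = labels.index(top)
    limited = set()
    for i, g in enumerate(labels):
        if g == top:
            continue
        if res.pvalue[i, top_idx] < alpha and means[g] < means[top]:
            limited.add(g)
    return DayPartition(day, frozenset(limited), frozenset(set(labels) - limited))


def critical_point_for_day(day_samples: pd.DataFrame,
                           partition: DayPartition) -> CriticalPoint:
    """Critical point of one sampling day from its N-limited / non-limited split.

    Ordinary least squares of N concentration on AGB over the limited samples;
    the day's maximum AGB is the mean AGB of the non-limited samples and the
    critical concentration is the fitted line evaluated there.
    """
    if not partition.non_limited:
        raise ValueError("non-limited group is empty")
    lim = day_samples[day_samples["gradient"].isin(partition.limited)]
    non = day_samples[day_samples["gradient"].isin(partition.non_limited)]
    agb = np.asarray(lim["agb_t_hm2"], dtype=float)
    n = np.asarray(lim["n_conc_pct"], dtype=float)
    if len(agb) < 2 or np.ptp(agb) == 0:
        raise DegenerateFitError(
            "need >= 2 N-limited observations with distinct AGB for the linear fit")
    slope, intercept = np.polyfit(agb, n, 1)
    agb_max = float(np.mean(non["agb_t_hm2"]))
    n_critical = float(intercept + slope * agb_max)
    if n_critical <= 0:
        raise DegenerateFitError(
            f"critical concentration non-positive ({n_critical:.3g}) at AGB={agb_max:.3g}")
    return CriticalPoint(day=partition.day, agb_max=agb_max, n_critical=n_critical)


def fit_critical_curve(points: list[CriticalPoint]) -> CriticalCurve:
    """Fit Nc = a * DM**(-b) through per-day critical points.

    Nonlinear least squares on the original concentration scale, initialized
    from an ordinary log–log regression. Returns the curve with its R² and
    RMSE (%) over the fitted points.
    """
    agb = np.array([p.agb_max for p in points], dtype=float)
    nc = np.array([p.n_critical for p in points], dtype=float)
    if len(np.unique(agb)) < 2:
        raise DegenerateFitError("need >= 2 critical points with distinct AGB")
    if np.any(agb <= 0) or np.any(nc <= 0):
        raise ValueError("critical points must have positive coordinates")

    # log-log OLS start: ln Nc = ln a - b ln DM
    slope, intercept = np.polyfit(np.log(agb), np.log(nc), 1)
    a0, b0 = float(np.exp(intercept)), float(max(-slope, 1e-3))

    def model(x, a, b):
        return a * x ** (-b)

    (a_hat, b_hat), _ = optimize.curve_fit(
        model, agb, nc, p0=(a0, b0), bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000)
    resid = nc - model(agb, a_hat, b_hat)
    sstot = float(np.sum((nc - nc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CriticalCurve(a=float(a_hat), b=float(b_hat), r2=r2, rmse=rmse)


def compute_nni(n_conc: float, agb: float, curve: CriticalCurve,
                sample_id: object = None) -> NniRecord:
    """NNI of one sample: measured N% over the critical N% at its biomass."""
    if n_conc <= 0 or agb <= 0:
        raise ValueError("N concentration and AGB must be positive")
    nni = float(n_conc / curve.critical_n(agb))
    return NniRecord(sample_id=sample_id, nni=nni)


def compute_nni_table(agronomy: pd.DataFrame, curve: CriticalCurve) -> pd.DataFrame:
    """Vectorized NNI over an agronomy table; adds ``nni`` and ``group`` columns."""
    nni = agronomy["n_conc_pct"].to_numpy(float) / np.asarray(
        curve.critical_n(agronomy["agb_t_hm2"].to_numpy(float)))
    out = agronomy[["sample_id"]].copy()
    out["nni"] = nni
    out["group"] = np.where(nni < 1.0, "deficit", "rich")
    return out
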