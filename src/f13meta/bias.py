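"""Publication-bias diagnostics: Egger regression, Begg-Mazumdar rank
correlation, and funnel-plot coordinates.

Egger's test regresses the standardized effect ``y_i/se_i`` on precision
``1/se_i`` by ordinary (unweighted) least squares; a non-zero intercept
indicates small-study asymmetry. The intercept CI and p use the t
distribution on k-2 df.

Begg's test rank-correlates variance-stabilised deviations from the
inverse-variance fixed pool with the study variances, using Kendall's
tau-b. Small study counts make the p value sensitive to the continuity
correction of the normal approximation, so both the uncorrected (primary)
and corrected p are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import EffectEstimate, InsufficientStudiesError, Z975, inverse_variance_fixed


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    ci_low: float
    ci_high: float
    p: float
    slope: float
    k: int


@dataclass(frozen=True)
class BeggResult:
    tau: float
    p: float          # normal approximation, no continuity correction
    p_corrected: float  # with continuity correction
    k: int


@dataclass(frozen=True)
class BiasTestResult:
    """Combined Egger + Begg block for one genetic model."""

    egger_intercept: float
    egger_ci_low: float
    egger_ci_high: float
    egger_p: float
    begg_tau: float
    begg_p: float
    begg_p_corrected: float
    k: int


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression asymmetry test (classic unweighted variant)."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Egger's test requires at least 3 studies")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects])
    x = 1.0 / se
    z = y / se
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all precisions identical")
    fit = stats.linregress(x, z)
    tq = stats.t.ppf(0.975, k - 2)
    t_stat = fit.intercept / fit.intercept_stderr
    p = 2.0 * float(stats.t.sf(abs(t_stat), k - 2))
    return EggerResult(
        intercept=float(fit.intercept),
        ci_low=float(fit.intercept - tq * fit.intercept_stderr),
        ci_high=float(fit.intercept + tq * fit.intercept_stderr),
        p=p,
        slope=float(fit.slope),
        k=k,
    )


def _kendall_s_and_var(u: np.ndarray, v: np.ndarray) -> tuple[int, float]:
    """Kendall S = concordant - discordant, and its tie-corrected variance."""
    n = len(u)
    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    s = int(np.sum(np.triu(du * dv, 1)))

    def tie_sizes(x):
        _, counts = np.unique(x, return_counts=True)
        return counts[counts > 1]

    t, g = tie_sizes(u), tie_sizes(v)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float(np.sum(t * (t - 1) * (2 * t + 5)))
    vg = float(np.sum(g * (g - 1) * (2 * g + 5)))
    var = (v0 - vt - vg) / 18.0
    if n > 2:
        var += (np.sum(t * (t - 1)) * np.sum(g * (g - 1))) / (2.0 * n * (n - 1))
        var += (np.sum(t * (t - 1) * (t - 2)) * np.sum(g * (g - 1) * (g - 2))) / (
            9.0 * n * (n - 1) * (n - 2))
    return s, var


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for funnel asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Begg's test requires at least 3 studies")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    y_fixed, _ = inverse_variance_fixed(effects)
    w_sum = float(np.sum(1.0 / v))
    u = (y - y_fixed) / np.sqrt(v - 1.0 / w_sum)

    tau = float(stats.kendalltau(u, v).statistic)
    s, var = _kendall_s_and_var(u, v)
    sd = math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(s) / sd))
    p_cc = 2.0 * float(stats.norm.sf(max(abs(s) - 1.0, 0.0) / sd))
    return BeggResult(tau=tau, p=min(p, 1.0), p_corrected=min(p_cc, 1.0), k=k)


def bias_tests(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    e = egger_test(effects)
    b = begg_test(effects)
    return BiasTestResult(
        egger_intercept=e.intercept, egger_ci_low=e.ci_low,
        egger_ci_high=e.ci_high, egger_p=e.p,
        begg_tau=b.tau, begg_p=b.p, begg_p_corrected=b.p_corrected,
        k=len(effects),
    )


@dataclass(frozen=True)
class FunnelData:
    """Per-study (log-OR, se) points and 95% pseudo-confidence boundaries."""

    points: pd.DataFrame       # study_id, log_or, se, or_
    center_log_or: float       # inverse-variance fixed pooled log-OR
    boundaries: pd.DataFrame   # se, lo, hi on the log-OR scale


def funnel_coordinates(effects: Sequence[EffectEstimate],
                       n_boundary: int = 50) -> FunnelData:
    """Coordinates for a standard funnel plot (se on the inverted y axis).

    The pseudo-confidence region fans out around the fixed pooled log-OR as
    ``center +/- 1.96 * se``; for a single study the fixed pool is that
    study, so the funnel is centred on it.
    """
    if not effects:
        raise InsufficientStudiesError("no effects")
    center, _ = inverse_variance_fixed(effects)
    points = pd.DataFrame({
        "study_id": [e.study_id for e in effects],
        "log_or": [e.log_or for e in effects],
        "se": [e.se for e in effects],
        "or_": [e.or_ for e in effects],
    })
    se_grid = np.linspace(0.0, 1.05 * points["se"].max(), n_boundary)
    boundaries = pd.DataFrame({
        "se": se_grid,
        "lo": center - Z975 * se_grid,
        "hi": center + Z975 * se_grid,
    })
    return FunnelData(points=points, center_log_or=center, boundaries=boundaries)
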