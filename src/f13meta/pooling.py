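"""Pooled odds ratios: Mantel-Haenszel fixed effects and DerSimonian-Laird
random effects, with Cochran's Q / I-squared / tau-squared heterogeneity.

Per-study effects are log odds ratios with Woolf variances,
``y = ln(ad/bc)``, ``var(y) = 1/a + 1/b + 1/c + 1/d``, computed on
continuity-corrected cells where a study required correction.

Conventions follow Cochrane/RevMan practice: the Mantel-Haenszel standard
error uses the Robins-Breslow-Greenland variance; heterogeneity (Q, tau^2)
is always computed from inverse-variance weights on the log-OR scale; the
95% CI multiplier is the normal 1.96 for both methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genetic_models import ContingencyTable

Z975 = 1.959963984540054  # normal 97.5th percentile

MH_FIXED = "MH_fixed"
DL_RANDOM = "DL_random"


class InsufficientStudiesError(ValueError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio and its Woolf standard error."""

    study_id: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.study_id}: standard error must be > 0")

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z975 * self.se)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with df = k-1, I^2 (%), DL moment tau^2, and the Q-test p."""

    q: float
    df: int
    i2: float
    tau2: float
    p_q: float


@dataclass(frozen=True)
class PooledResult:
    method: str
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: HeterogeneityStats
    weights: tuple[tuple[str, float], ...]  # (study_id, normalised %)
    k: int

    @property
    def log_or(self) -> float:
        return math.log(self.pooled_or)

    @property
    def significant(self) -> bool:
        """CI excludes the null odds ratio of 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def study_effect(t: ContingencyTable) -> EffectEstimate:
    """Log odds ratio with Woolf variance from one 2x2 table."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ValueError(
            f"{t.study_id}: zero cell without continuity correction"
        )
    y = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EffectEstimate(t.study_id, y, se)


def _effects(tables: Sequence[ContingencyTable]) -> list[EffectEstimate]:
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    return [study_effect(t) for t in tables]


def _het_from_effects(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    if k == 1:
        return HeterogeneityStats(q=0.0, df=0, i2=0.0, tau2=0.0, p_q=1.0)
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    p_q = float(stats.chi2.sf(q, df))
    return HeterogeneityStats(q=q, df=df, i2=i2, tau2=tau2, p_q=p_q)


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q around the inverse-variance fixed pool; requires k >= 2."""
    if len(effects) < 2:
        raise InsufficientStudiesError("heterogeneity undefined for k < 2")
    return _het_from_effects(effects)


def _finish(method, log_or, se, het, ids, w, k) -> PooledResult:
    z = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    pct = tuple(zip(ids, (100.0 * w / np.sum(w)).tolist()))
    return PooledResult(
        method=method,
        pooled_or=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        z=z, p=p, het=het, weights=pct, k=k,
    )


def pool_fixed_mh(tables: Sequence[ContingencyTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the standard error
    of its log is the Robins-Breslow-Greenland estimator. Cells are used as
    stored: uncorrected for studies that needed no correction, corrected
    (+0.5) only where a single-arm zero forced it.
    """
    effects = _effects(tables)
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d

    r = a * d / n
    s = b * c / n
    R, S = float(np.sum(r)), float(np.sum(s))
    if R <= 0 or S <= 0:
        raise ValueError("Mantel-Haenszel pool degenerate: no discordant cells")
    log_or = math.log(R / S)

    p_ = (a + d) / n
    q_ = (b + c) / n
    var = (float(np.sum(p_ * r)) / (2 * R**2)
           + float(np.sum(p_ * s + q_ * r)) / (2 * R * S)
           + float(np.sum(q_ * s)) / (2 * S**2))
    se = math.sqrt(var)

    het = _het_from_effects(effects)
    ids = [t.study_id for t in tables]
    return _finish(MH_FIXED, log_or, se, het, ids, s, len(tables))


def pool_random_dl(tables: Sequence[ContingencyTable]) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    The moment estimator ``tau^2 = max(0, (Q - (k-1)) / (sum(w) -
    sum(w^2)/sum(w)))`` with inverse-variance weights ``w_i = 1/se_i^2``
    inflates each study's variance; with a single study or Q <= k-1 it
    reduces to inverse-variance fixed pooling.
    """
    effects = _effects(tables)
    het = _het_from_effects(effects)
    y = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w_star = 1.0 / (v + het.tau2)
    log_or = float(np.sum(w_star * y) / np.sum(w_star))
    se = 1.0 / math.sqrt(float(np.sum(w_star)))
    ids = [e.study_id for e in effects]
    return _finish(DL_RANDOM, log_or, se, het, ids, w_star, len(tables))


def pool(tables: Sequence[ContingencyTable], method: str) -> PooledResult:
    """Dispatch to :func:`pool_fixed_mh` or :func:`pool_random_dl`."""
    if method == MH_FIXED:
        return pool_fixed_mh(tables)
    if method == DL_RANDOM:
        return pool_random_dl(tables)
    raise ValueError(f"unknown pooling method {method!r}")


def select_method(het: HeterogeneityStats, i2_threshold: float = 50.0) -> str:
    """Random effects when I^2 reaches the threshold (inclusive), else MH.

    The 50% default corresponds to the conventional 'intermediate
    inconsistency' boundary on the I^2 scale.
    """
    return DL_RANDOM if het.i2 >= i2_threshold else MH_FIXED


def inverse_variance_fixed(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Inverse-variance fixed pooled (log_or, se); used by the bias tests."""
    if not effects:
        raise InsufficientStudiesError("no effects to pool")
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    return float(np.sum(w * y) / np.sum(w)), 1.0 / math.sqrt(float(np.sum(w)))
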