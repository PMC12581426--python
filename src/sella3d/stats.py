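"""Agreement, classification and group-comparison statistics.

Implements the statistical layer of the morphometric study: Bland–Altman
limits of agreement, skeletal classification from the three cephalometric
covariates, Kruskal–Wallis tests with Dunn/Bonferroni post-hoc comparisons,
Spearman rank correlation, and the Cohen's-d / noncentral-t sample-size
computation. Sample standard deviations use the n−1 denominator throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BAResult",
    "ClassLabels",
    "PowerSpec",
    "KWResult",
    "bland_altman",
    "classify_sagittal",
    "classify_vertical",
    "classify_transverse",
    "classify_labels",
    "cohens_d_pooled",
    "power_two_sample_t",
    "sample_size_two_group_t",
    "kruskal_wallis",
    "dunn_bonferroni",
    "spearman_rho",
]

#: Limits-of-agreement multiplier (normal 95% coverage). Fixed: it reproduces
#: every printed agreement row of the study at two decimals.
LOA_MULTIPLIER = 1.96

# classification cut-offs
WITS_CLASS_I = (-2.0, 2.0)        # mm, closed interval
MLNL_NEUTRAL = (20.5, 26.5)       # degrees, closed interval
MEMSP_SYMMETRIC_MAX = 2.0         # mm, inclusive


@dataclass(frozen=True)
class BAResult:
    """Bland–Altman agreement summary for paired measurements x − y."""

    mean_diff: float
    sd: float
    loa_upper: float
    loa_lower: float
    n: int
    frac_within_loa: float


@dataclass(frozen=True)
class ClassLabels:
    sagittal: str    # "I" | "II" | "III"
    vertical: str    # "neutral" | "hypodivergent" | "hyperdivergent"
    transverse: str  # "symmetric" | "asymmetric"


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-group sample-size computation.

    Either supply the standardized effect ``d`` directly or the two group
    summaries (m1, s1, m2, s2) from which it is pooled.
    """

    alpha: float = 0.05
    power: float = 0.90
    d: float | None = None
    m1: float | None = None
    s1: float | None = None
    m2: float | None = None
    s2: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.d is None and None in (self.m1, self.s1, self.m2, self.s2):
            raise ValueError("provide either d or all of m1, s1, m2, s2")

    def effect_size(self) -> float:
        if self.d is not None:
            return float(self.d)
        return cohens_d_pooled(self.m1, self.s1, self.m2, self.s2)


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


def bland_altman(x, y) -> BAResult:
    """Bland–Altman analysis of paired measurements.

    Differences are ``x - y``; the limits of agreement are
    ``mean ± 1.96 · SD`` with the sample (n−1) standard deviation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper = mean_diff + LOA_MULTIPLIER * sd
    lower = mean_diff - LOA_MULTIPLIER * sd
    within = float(np.mean((d >= lower) & (d <= upper)))
    return BAResult(
        mean_diff=mean_diff, sd=sd, loa_upper=upper, loa_lower=lower,
        n=int(x.size), frac_within_loa=within,
    )


def _check_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite (got {value})")
    return value


def classify_sagittal(wits: float) -> str:
    """Skeletal class from the Wits appraisal: I on [−2, 2] mm, II above, III below."""
    wits = _check_finite(wits, "wits")
    if WITS_CLASS_I[0] <= wits <= WITS_CLASS_I[1]:
        return "I"
    return "II" if wits > WITS_CLASS_I[1] else "III"


def classify_vertical(mlnl: float) -> str:
    """Vertical type from the maxillomandibular plane angle (neutral on [20.5°, 26.5°])."""
    mlnl = _check_finite(mlnl, "mlnl")
    if MLNL_NEUTRAL[0] <= mlnl <= MLNL_NEUTRAL[1]:
        return "neutral"
    return "hypodivergent" if mlnl < MLNL_NEUTRAL[0] else "hyperdivergent"


def classify_transverse(memsp: float) -> str:
    """Transverse symmetry from menton deviation (symmetric when ≤ 2 mm)."""
    memsp = _check_finite(memsp, "memsp")
    return "symmetric" if memsp <= MEMSP_SYMMETRIC_MAX else "asymmetric"


def classify_labels(wits: float, mlnl: float, memsp: float) -> ClassLabels:
    return ClassLabels(
        sagittal=classify_sagittal(wits),
        vertical=classify_vertical(mlnl),
        transverse=classify_transverse(memsp),
    )


def cohens_d_pooled(m1: float, s1: float, m2: float, s2: float) -> float:
    """|m1 − m2| / sqrt((s1² + s2²) / 2), the equal-weight pooled-SD convention."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(m1 - m2) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)


def power_two_sample_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test at n per group.

    Under the alternative the statistic follows a noncentral t with
    noncentrality ``d·sqrt(n/2)`` and ``2n − 2`` degrees of freedom.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
    )


def sample_size_two_group_t(spec: PowerSpec) -> int:
    """Smallest per-group n whose exact noncentral-t power reaches spec.power."""
    d = spec.effect_size()
    if d == 0:
        raise ValueError("effect size d = 0: requested power is unattainable")
    n = 2
    while power_two_sample_t(n, d, spec.alpha) < spec.power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample size search did not converge")
    return n


def _clean_groups(groups) -> list[np.ndarray]:
    cleaned = [np.asarray(g, dtype=float).ravel() for g in groups]
    return [g for g in cleaned if g.size > 0]


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p (k − 1 df)."""
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    total_n = sum(g.size for g in cleaned)
    if total_n < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(cleaned) - 1
    pooled = np.concatenate(cleaned)
    if np.ptp(pooled) == 0:  # scipy rejects all-identical data; H is 0 by definition
        return KWResult(h=0.0, df=df, p=1.0, group_sizes=tuple(g.size for g in cleaned))
    h, p = sps.kruskal(*cleaned)
    return KWResult(h=float(h), df=df, p=float(p), group_sizes=tuple(g.size for g in cleaned))


def dunn_bonferroni(groups, labels=None) -> pd.DataFrame:
    """Dunn's rank z-tests for all pairs, Bonferroni-adjusted.

    Uses the pooled mid-ranks with tie correction; raw two-sided p-values are
    multiplied by the number of pairs and capped at 1.
    """
    cleaned = _clean_groups(groups)
    k = len(cleaned)
    if k < 3:
        raise ValueError("post-hoc comparisons need at least 3 groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of non-empty groups")

    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in cleaned])
    mean_ranks = [
        float(np.mean(ranks[bounds[i]:bounds[i + 1]])) for i in range(k)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(base_var * (1.0 / cleaned[i].size + 1.0 / cleaned[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "group_a": labels[i],
            "group_b": labels[j],
            "z": z,
            "p_raw": p_raw,
            "p_adj": min(1.0, p_raw * n_pairs),
        })
    return pd.DataFrame(rows)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's ρ (Pearson correlation of mid-ranks) with a t-approximation p."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation is undefined for a constant input vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
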