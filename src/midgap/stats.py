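"""Statistical comparisons for gap and count data.

Fisher's exact test (two-sided, point-probability rule) is implemented
directly on log-factorial hypergeometric probabilities; one-way ANOVA,
Tukey's HSD and the Welch t-test wrap scipy.stats.  Bonferroni
correction multiplies raw p-values by the number of tests, capped at 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "Table2x2",
    "FisherResult",
    "AnovaResult",
    "fisher_exact",
    "anova_oneway",
    "tukey_hsd",
    "ttest_bonferroni",
]

logger = logging.getLogger(__name__)

#: relative tolerance for pmf ties in the two-sided Fisher rule
FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("all-zero table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float


def _log_hypergeom_pmf(x: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    # log C(r1, x) + log C(r2, c1-x) - log C(r1+r2, c1)
    n = r1 + r2

    def logc(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logc(r1, x) + logc(r2, c1 - x) - logc(n, c1)


def fisher_exact(t: Table2x2) -> FisherResult:
    """Two-sided Fisher's exact test by the point-probability method.

    p is the sum of hypergeometric probabilities, over all tables with
    the observed margins, of tables whose point probability does not
    exceed the observed one (within a relative tie tolerance of 1e-7).
    """
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, r1, r2, c1)
    log_obs = float(_log_hypergeom_pmf(np.array([t.a]), r1, r2, c1)[0])
    keep = logpmf <= log_obs + np.log1p(FISHER_TIE_RTOL)
    p = float(np.exp(logpmf[keep]).sum())
    if t.b * t.c == 0:
        odds = np.inf if t.a * t.d > 0 else np.nan
    else:
        odds = (t.a * t.d) / (t.b * t.c)
    return FisherResult(p_value=min(p, 1.0), odds_ratio=odds)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def _validated_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has n < 2")
        out[label] = arr
    pooled = np.concatenate(list(out.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("zero total variance: F statistic undefined")
    return out

def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across labelled groups."""
    g = _validated_groups(groups)
    f, p = sps.f_oneway(*g.values())
    k = len(g)
    n = sum(a.size for a in g.values())
    return AnovaResult(
        f_statistic=float(f), p_value=float(p), df_between=k - 1, df_within=n - k
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey's HSD adjusted p for every group pair.

    All pairs are reported regardless of the omnibus ANOVA outcome.
    Columns: group1, group2, mean_diff, p_adj.
    """
    g = _validated_groups(groups)
    labels = list(g.keys())
    res = sps.tukey_hsd(*g.values())
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": float(g[labels[i]].mean() - g[labels[j]].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_raw: float
    p_adj: float


def ttest_bonferroni(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    m: int | None = None,
    equal_var: bool = False,
) -> list[TTestResult]:
    """Two-tailed t-tests (Welch by default) with Bonferroni correction.

    ``m`` defaults to the number of pairs and must be at least that.
    Degenerate pairs (zero variance on both sides with equal means) get
    p = 1 by convention and are logged.
    """
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise ValueError("m must be >= number of tests")
    results = []
    for x, y in pairs:
        xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if xa.size < 2 or ya.size < 2:
            raise ValueError("each sample needs n >= 2")
        if xa.std() == 0 and ya.std() == 0 and xa.mean() == ya.mean():
            logger.warning("degenerate pair (zero variance, equal means): p = 1 by convention")
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(xa, ya, equal_var=equal_var)
        results.append(
            TTestResult(statistic=float(stat), p_raw=float(p), p_adj=min(float(p) * m, 1.0))
        )
    return results
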