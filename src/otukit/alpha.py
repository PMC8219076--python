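"""Per-sample alpha-diversity estimators and between-group univariate tests.

Estimator conventions (these are conventions of this package, stated once):

* Shannon entropy uses the natural log by default (``base`` overrides).
* Simpson is reported as the *dominance* index ``D = sum n_i(n_i-1)/(N(N-1))``
  — lower means more diverse.
* Chao1 uses the bias-corrected ``+1`` denominator so it is defined when no
  doubletons are present.
* ACE uses the standard abundance cutoff of 10 reads for the rare class;
  when every rare read is a singleton its coverage term is zero, and the
  estimator falls back to Chao1 with a flag on the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "observed_richness",
    "goods_coverage",
    "chao1",
    "ace",
    "AceResult",
    "shannon",
    "simpson",
    "alpha_diversity",
    "GroupTestResult",
    "group_test",
    "pairwise_tests",
    "star_from_p",
]


def _counts(sample) -> np.ndarray:
    c = np.asarray(sample, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty sample (no positive counts)")
    return c


def observed_richness(sample) -> int:
    """Number of taxa with at least one read."""
    return int(_counts(sample).size)


def goods_coverage(sample) -> float:
    """Good's coverage 1 - F1/N, F1 = number of singletons, N = total reads."""
    c = _counts(sample)
    return float(1.0 - (c == 1).sum() / c.sum())


def chao1(sample) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = _counts(sample)
    f1 = float((c == 1).sum())
    f2 = float((c == 2).sum())
    return float(c.size + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0)))


@dataclass(frozen=True)
class AceResult:
    value: float
    chao1_fallback: bool = False

    def __float__(self) -> float:
        return self.value


def ace(sample, rare_cutoff: int = 10) -> AceResult:
    """ACE richness estimator with abundance cutoff ``rare_cutoff``.

    S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2, where C_ace = 1 - F1/N_rare
    and gamma^2 is the (non-negative) squared coefficient of variation of the
    rare-taxon abundances.  Falls back to Chao1 when C_ace = 0.
    """
    c = _counts(sample)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return AceResult(float(s_abund))
    n_rare = rare.sum()
    f1 = float((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return AceResult(chao1(sample), chao1_fallback=True)
    freq = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)], dtype=float)
    i = np.arange(1, rare_cutoff + 1, dtype=float)
    gamma2 = (s_rare / c_ace) * (i * (i - 1.0) @ freq) / (n_rare * (n_rare - 1.0)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return AceResult(float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2))


def shannon(sample, base: float | None = None) -> float:
    """Shannon entropy H' = -sum p_i log p_i over taxa with p_i > 0."""
    c = _counts(sample)
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(sample) -> float:
    """Simpson dominance D = sum n_i(n_i-1) / (N(N-1)); lower = more diverse."""
    c = _counts(sample)
    n = c.sum()
    if n < 2:
        raise ValueError("Simpson dominance needs at least 2 reads")
    return float((c * (c - 1.0)).sum() / (n * (n - 1.0)))


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """All estimators for every sample of a count table.

    Returns a DataFrame indexed by sample id with columns ``observed``,
    ``coverage``, ``chao1``, ``ace``, ``ace_chao1_fallback``, ``shannon``,
    ``simpson``.
    """
    rows = {}
    for sid in table.columns:
        col = table[sid].to_numpy()
        a = ace(col)
        rows[sid] = {
            "observed": observed_richness(col),
            "coverage": goods_coverage(col),
            "chao1": chao1(col),
            "ace": a.value,
            "ace_chao1_fallback": a.chao1_fallback,
            "shannon": shannon(col),
            "simpson": simpson(col),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def star_from_p(p: float) -> str:
    """Significance stars: * 0.01<P<=0.05, ** 0.001<P<=0.01, *** P<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupTestResult:
    statistic_name: str  # one of {"t", "F", "H"}
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    star: str


_STAT_NAMES = {"t": "t", "anova": "F", "kruskal": "H"}


def group_test(
    values_by_group: Mapping[str, Sequence[float]], test: str = "t"
) -> GroupTestResult:
    """Two-sided comparison of per-group values.

    ``test`` is one of ``t`` (Student's t, exactly 2 groups), ``anova``
    (one-way F) or ``kruskal`` (Kruskal-Wallis H with midranks and tie
    correction).  When every value is identical across groups the test is
    degenerate and the contract is statistic 0, p = 1.
    """
    if test not in _STAT_NAMES:
        raise ValueError(f"unknown test {test!r}")
    names = tuple(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if test == "t" and len(groups) != 2:
        raise ValueError("t-test requires exactly 2 groups")
    if test in ("t", "anova") and any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if any(g.size < 1 for g in groups):
        raise ValueError("empty group")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(_STAT_NAMES[test], 0.0, 1.0, names, "ns")

    if test == "t":
        stat, p = stats.ttest_ind(groups[0], groups[1])
    elif test == "anova":
        stat, p = stats.f_oneway(*groups)
    else:
        stat, p = stats.kruskal(*groups)
    stat, p = float(stat), float(p)
    if np.isnan(p):  # zero variance within each group but unequal means
        p = 0.0 if test == "t" else p
        stat = np.inf
    return GroupTestResult(_STAT_NAMES[test], stat, p, names, star_from_p(p))


def pairwise_tests(
    alpha_df: pd.DataFrame,
    info: pd.DataFrame,
    by: str = "habitat",
    metrics: Sequence[str] = ("chao1", "ace", "shannon", "simpson"),
    test: str = "t",
) -> pd.DataFrame:
    """All pairwise group comparisons per alpha metric (default: t-tests).

    Returns one row per (metric, group pair) with statistic, p and stars.
    """
    levels = list(dict.fromkeys(info.loc[alpha_df.index, by]))
    rows = []
    for metric in metrics:
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                va = alpha_df.loc[info.index[info[by] == a].intersection(alpha_df.index), metric]
                vb = alpha_df.loc[info.index[info[by] == b].intersection(alpha_df.index), metric]
                res = group_test({a: va.to_numpy(), b: vb.to_numpy()}, test=test)
                rows.append(
                    {
                        "metric": metric,
                        "group1": a,
                        "group2": b,
                        "statistic_name": res.statistic_name,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "star": res.star,
                    }
                )
    return pd.DataFrame(rows)
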