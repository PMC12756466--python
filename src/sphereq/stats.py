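"""Group-comparison statistics for per-neurosphere and per-spheroid metrics.

Omnibus tests (Kruskal-Wallis or one-way ANOVA) are followed by post hoc
pairwise tests (Dunn's rank-based z tests or Tukey's HSD; Mann-Whitney for
simple pairwise designs), with Holm step-down adjustment applied within each
pairwise family.  All tests are two-sided; significance is called at
alpha = 0.05, with conventional star thresholds at 0.01/0.001/0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "omnibus_compare",
    "posthoc_pairwise",
    "holm_adjust",
    "adjust_family",
    "significance_stars",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class GroupSample:
    """A labeled group of measurements (counts, proportions, or distances)."""

    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"group {self.group_label!r} is empty")
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.group_label!r} contains non-finite values")


@dataclass
class ComparisonResult:
    test_name: str
    groups: list[str]
    statistic: float
    p_raw: float
    p_adjusted: float = field(default=np.nan)
    significant: bool = False

    def finalize(self) -> "ComparisonResult":
        if np.isnan(self.p_adjusted):
            self.p_adjusted = self.p_raw
        self.significant = bool(self.p_adjusted < ALPHA)
        return self


def significance_stars(p: float) -> str:
    """Star notation at the conventional thresholds 0.05/0.01/0.001/0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _check_groups(samples, min_per_group=2):
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if s.values.size < min_per_group:
            raise ValueError(
                f"group {s.group_label!r} has {s.values.size} value(s); "
                f"need >= {min_per_group}"
            )


def omnibus_compare(samples: list[GroupSample], method: str = "kruskal") -> ComparisonResult:
    """Omnibus comparison of >= 2 groups.

    ``"kruskal"`` runs the Kruskal-Wallis H test with mid-rank tie correction;
    ``"anova"`` a one-way fixed-effects ANOVA.
    """
    _check_groups(samples)
    arrays = [s.values for s in samples]
    if method == "kruskal":
        # degenerate all-identical case: H = 0, p = 1 (scipy raises instead)
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*arrays)
    elif method == "anova":
        stat, p = sps.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown omnibus method {method!r}")
    return ComparisonResult(
        test_name=method,
        groups=[s.group_label for s in samples],
        statistic=float(stat),
        p_raw=float(p),
    ).finalize()


def _dunn_pairwise(samples: list[GroupSample]) -> list[ComparisonResult]:
    """Dunn's rank-based z tests on the pooled mid-ranks, with tie correction."""
    values = np.concatenate([s.values for s in samples])
    ranks = sps.rankdata(values)
    n_total = values.size
    idx = np.cumsum([0] + [s.values.size for s in samples])
    mean_ranks = [
        ranks[idx[i]: idx[i + 1]].mean() for i in range(len(samples))
    ]
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    results = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        ni, nj = samples[i].values.size, samples[j].values.size
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            ComparisonResult(
                test_name="dunn",
                groups=[samples[i].group_label, samples[j].group_label],
                statistic=float(z),
                p_raw=float(min(1.0, p)),
            )
        )
    return results


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small untied samples,
    normal approximation with tie correction otherwise."""
    exact = x.size <= 8 and y.size <= 8 and np.unique(np.concatenate([x, y])).size == x.size + y.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def posthoc_pairwise(samples: list[GroupSample], method: str = "dunn") -> list[ComparisonResult]:
    """One two-sided result per unordered group pair (raw p-values).

    Use :func:`adjust_family` to Holm-adjust the returned family.
    """
    _check_groups(samples)
    if method == "dunn":
        results = [r.finalize() for r in _dunn_pairwise(samples)]
    elif method == "tukey":
        res = sps.tukey_hsd(*[s.values for s in samples])
        results = []
        for i, j in itertools.combinations(range(len(samples)), 2):
            results.append(
                ComparisonResult(
                    test_name="tukey",
                    groups=[samples[i].group_label, samples[j].group_label],
                    statistic=float(res.statistic[i, j]),
                    p_raw=float(res.pvalue[i, j]),
                ).finalize()
            )
    elif method == "mannwhitney":
        results = []
        for i, j in itertools.combinations(range(len(samples)), 2):
            stat, p = _mannwhitney(samples[i].values, samples[j].values)
            results.append(
                ComparisonResult(
                    test_name="mannwhitney",
                    groups=[samples[i].group_label, samples[j].group_label],
                    statistic=stat,
                    p_raw=p,
                ).finalize()
            )
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return results


def holm_adjust(p_raw) -> list[float]:
    """Holm step-down adjustment, returned in the original order.

    With p-values sorted ascending, the i-th adjusted value is
    ``max_{j<=i} min(1, (m - j + 1) * p_(j))`` — monotone along the sorted
    order and capped at 1.
    """
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return [float(x) for x in out]


def adjust_family(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Holm-adjust a family of pairwise results in place (and re-call
    significance); returns the same list for chaining."""
    adj = holm_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = a
        r.significant = bool(a < ALPHA)
    return results
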