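"""Classifier-comparison statistics: Lilliefors → one-way ANOVA → Tukey HSD.

The workflow applied to an accuracy table (classifiers × experimental
conditions, percentages): each classifier's row is first checked for
normality with a Lilliefors test (Monte-Carlo p-values); rows failing the
gate — or rows pinned by the caller — are excluded; a one-way ANOVA is
run across the remaining classifiers; if it rejects, Tukey's studentized
range procedure decides which classifiers differ, and the "best set" is
the top performer together with every classifier not significantly below
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

DEFAULT_ALPHA = 0.05
DEFAULT_MC_REPLICATES = 10_000

# Null tables for the Lilliefors statistic are expensive; they depend only
# on (n, n_mc, seed), so memoise them.
_LILLIEFORS_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


@dataclass(frozen=True)
class LillieforsResult:
    statistic: float
    p_value: float
    reject: bool
    alpha: float


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p_value: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass(frozen=True)
class TukeyResult:
    labels: tuple[str, ...]
    means: np.ndarray
    mean_differences: np.ndarray      # k×k antisymmetric
    significant: np.ndarray           # k×k boolean, symmetric
    hsd: float                        # critical |mean difference|
    best_set: tuple[str, ...]


def _lilliefors_statistic(samples: np.ndarray) -> np.ndarray:
    """Sup distance between row ECDFs and per-row fitted normal CDFs.

    ``samples`` is (R, n); returns R statistics (vectorised over rows).
    """
    x = np.sort(samples, axis=-1)
    n = x.shape[-1]
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    z = spstats.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=-1)
    d_minus = (z - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_NULL_CACHE:
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_mc, n))
        _LILLIEFORS_NULL_CACHE[key] = np.sort(_lilliefors_statistic(sims))
    return _LILLIEFORS_NULL_CACHE[key]


def lilliefors_test(
    sample,
    alpha: float = DEFAULT_ALPHA,
    n_mc: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> LillieforsResult:
    """Normality test with mean and SD estimated from the sample.

    The p-value is Monte-Carlo: the fraction of ``n_mc`` seeded standard
    normal samples of the same size whose statistic is at least as large
    (with the +1 continuity correction).
    """
    x = np.asarray(sample, dtype=np.float64).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) < 1e-12:
        raise ValueError("sample has zero variance")
    stat = float(_lilliefors_statistic(x[None, :])[0])
    null = _lilliefors_null(x.size, n_mc, seed)
    n_ge = null.size - np.searchsorted(null, stat, side="left")
    p = (n_ge + 1) / (n_mc + 1)
    return LillieforsResult(stat, float(p), bool(p < alpha), alpha)


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way decomposition; p from the F distribution."""
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_between = len(gs) - 1
    df_within = allv.size - len(gs)
    if ss_within < 1e-12:
        raise ValueError("zero within-group variance: F undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(spstats.f.sf(F, df_between, df_within))
    return AnovaResult(ss_between, ss_within, df_between, df_within, float(F), p)


def tukey_hsd(groups, alpha: float = DEFAULT_ALPHA, labels=None) -> TukeyResult:
    """All-pairs comparison by the studentized range criterion (equal n).

    Uses the ANOVA within-group mean square; a pair differs significantly
    when |mean difference| exceeds q_{1-α;k,df} · sqrt(MS_within / n).
    """
    gs = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    sizes = {g.size for g in gs}
    if len(sizes) != 1:
        raise ValueError("tukey_hsd requires equal group sizes")
    n = gs[0].size
    k = len(gs)
    labels = tuple(labels) if labels is not None else tuple(f"g{i}" for i in range(k))
    if len(labels) != k:
        raise ValueError("label count must match group count")
    anova = one_way_anova(gs)
    q_crit = float(spstats.studentized_range.ppf(1 - alpha, k, anova.df_within))
    hsd = q_crit * np.sqrt(anova.ms_within / n)
    means = np.array([g.mean() for g in gs])
    diff = means[:, None] - means[None, :]
    sig = np.abs(diff) > hsd
    np.fill_diagonal(sig, False)
    best_idx = int(np.argmax(means))
    best_set = tuple(labels[j] for j in range(k) if not sig[best_idx, j])
    return TukeyResult(labels, means, diff, sig, float(hsd), best_set)


@dataclass(frozen=True)
class ComparisonReport:
    """Record of every decision taken by the comparison workflow."""

    lilliefors: dict = field(default_factory=dict)   # row label → LillieforsResult
    excluded: tuple[str, ...] = ()
    anova: AnovaResult | None = None
    anova_rejects: bool = False
    tukey: TukeyResult | None = None
    best_set: tuple[str, ...] = ()


def compare_classifiers(
    rows: dict[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    excluded: list[str] | None = None,
    n_mc: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> ComparisonReport:
    """Lilliefors gate → ANOVA → Tukey on a classifier → accuracies map.

    If ``excluded`` is given it pins the exclusion set (the Lilliefors
    results are still reported); otherwise rows rejected by the test at
    ``alpha`` are dropped.  Tukey runs only when the ANOVA rejects; then
    ``best_set`` holds the top classifier and everything statistically
    level with it.  With a non-significant ANOVA the best set is empty
    (no classifier separates from the rest).
    """
    lill = {
        name: lilliefors_test(vals, alpha=alpha, n_mc=n_mc, seed=seed)
        for name, vals in rows.items()
    }
    if excluded is None:
        excluded_t = tuple(name for name, res in lill.items() if res.reject)
    else:
        unknown = set(excluded) - set(rows)
        if unknown:
            raise ValueError(f"unknown classifiers in exclusion list: {sorted(unknown)}")
        excluded_t = tuple(excluded)
    kept = {name: vals for name, vals in rows.items() if name not in excluded_t}
    if len(kept) < 2:
        raise ValueError("fewer than 2 classifiers remain after exclusion")
    anova = one_way_anova(list(kept.values()))
    rejects = anova.p_value < alpha
    tukey = None
    best: tuple[str, ...] = ()
    if rejects:
        tukey = tukey_hsd(list(kept.values()), alpha=alpha, labels=list(kept))
        best = tukey.best_set
    return ComparisonReport(lill, excluded_t, anova, rejects, tukey, best)
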