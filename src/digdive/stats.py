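"""Statistical procedures for behavioral group comparisons.

Normality-gated test selection (Lilliefors, then Student t or
Mann-Whitney), Kruskal-Wallis with Bonferroni-corrected pairwise post
hocs and a compact letter display, two-sample Kolmogorov-Smirnov,
Cohen's d, noncentral-t power and sample-size search, and the simple
assay formulas (preference index, survival ratio, mouth-hook
contraction rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PowerSpec",
    "TestResult",
    "lilliefors_test",
    "rank_sum_test",
    "kruskal_posthoc",
    "KruskalPosthocResult",
    "ks_two_sample",
    "one_sample_t",
    "two_sample_t",
    "cohens_d",
    "t_power",
    "sample_size_t",
    "select_test",
    "preference_index",
    "survival_ratio",
    "mhc_rate",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a t-test power / sample-size computation.

    ``mu`` and ``sigma`` are the suspected mean and standard deviation,
    ``delta`` the difference worth detecting; the standardized effect
    is d = |delta| / sigma.
    """

    mu: float
    sigma: float
    delta: float
    power: float = 0.8
    alpha: float = 0.05
    sides: int = 2
    family: str = "one-sample-t"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0 < self.power < 1:
            raise ValidationError("power must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sides not in (1, 2):
            raise ValidationError("sides must be 1 or 2")
        if self.family not in ("one-sample-t", "two-sample-t"):
            raise ValidationError(f"unknown test family {self.family!r}")

    @property
    def effect_size(self) -> float:
        return abs(self.delta) / self.sigma


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: tuple[int, ...]
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------


def lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance between the ECDF and a normal fit to the same sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors_test(x: np.ndarray, n_mc: int = 10000, seed: int | None = 0) -> float:
    """Monte-Carlo Lilliefors normality test; returns the p-value.

    The null distribution of the KS distance is simulated from Gaussian
    samples of the same size with mean and sd re-estimated per
    replicate, which accounts for the parameter estimation that makes
    standard KS tables invalid here.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("lilliefors_test needs at least 4 observations")
    if np.std(x, ddof=1) == 0:
        raise ValidationError("degenerate sample (zero standard deviation)")
    d_obs = lilliefors_statistic(x)
    rng = np.random.default_rng(seed)
    n = x.size
    sims = rng.standard_normal((n_mc, n))
    sims.sort(axis=1)
    means = sims.mean(axis=1, keepdims=True)
    sds = sims.std(axis=1, ddof=1, keepdims=True)
    z = (sims - means) / sds
    cdf = stats.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_null = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    return float((np.count_nonzero(d_null >= d_obs) + 1) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Two-sample and multi-group comparisons
# ---------------------------------------------------------------------------


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for pooled sizes up to 12 without ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    Identical U and its mean give p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("rank_sum_test needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if abs(res.statistic - x.size * y.size / 2) < 1e-12:
        p = 1.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(p, 1.0),
        test_name=f"mann-whitney-{method}",
        n=(int(x.size), int(y.size)),
    )


@dataclass(frozen=True)
class KruskalPosthocResult:
    kruskal_statistic: float
    kruskal_p: float
    pairwise_p: np.ndarray  # Bonferroni-corrected, symmetric, diag NaN
    letters: tuple[str, ...]
    alpha: float = 0.05
    field_names: tuple[str, ...] = field(default=())


def compact_letter_display(ns_matrix: np.ndarray) -> list[str]:
    """Letters from the not-significantly-different adjacency matrix.

    Each letter corresponds to a maximal clique of the NS graph, so two
    groups share a letter iff they are not significantly different.
    """
    k = ns_matrix.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if ns_matrix[i, j]:
                g.add_edge(i, j)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)), key=lambda c: (c[0], c)
    )
    letters = [""] * k
    for idx, clique in enumerate(cliques):
        ch = chr(ord("a") + idx)
        for m in clique:
            letters[m] += ch
    return letters


def kruskal_posthoc(groups: list[np.ndarray], alpha: float = 0.05) -> KruskalPosthocResult:
    """Kruskal-Wallis plus Bonferroni-corrected pairwise rank-sum tests.

    Pairwise p-values are multiplied by the number of pairs (capped at
    1).  The compact letter display assigns letters so that two groups
    share a letter iff their corrected p >= alpha.
    """
    if len(groups) < 2:
        raise ValidationError("kruskal_posthoc needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs at least 2 observations")
    kw = stats.kruskal(*groups)
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            p = rank_sum_test(groups[i], groups[j]).p_value
            pmat[i, j] = pmat[j, i] = min(1.0, p * n_pairs)
    ns = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            ns[i, j] = i != j and pmat[i, j] >= alpha
    letters = compact_letter_display(ns)
    return KruskalPosthocResult(
        kruskal_statistic=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        pairwise_p=pmat,
        letters=tuple(letters),
        alpha=alpha,
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("ks_two_sample needs at least 2 observations per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        test_name="kolmogorov-smirnov",
        n=(int(x.size), int(y.size)),
    )


# ---------------------------------------------------------------------------
# t-tests, effect size, power
# ---------------------------------------------------------------------------


def one_sample_t(x: np.ndarray, mu0: float) -> TestResult:
    """Two-sided one-sample Student t-test against the mean mu0."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("one_sample_t needs at least 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValidationError("degenerate sample (zero standard deviation)")
    res = stats.ttest_1samp(x, mu0)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="one-sample-t",
        n=(int(x.size),),
        effect_size=abs(float(x.mean()) - mu0) / sd,
    )


def two_sample_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided two-sample Student t-test (pooled variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("two_sample_t needs at least 2 observations per sample")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="two-sample-t",
        n=(int(x.size), int(y.size)),
        effect_size=cohens_d(x, y),
    )


def cohens_d(x: np.ndarray, y: np.ndarray, denominator: str = "pooled") -> float:
    """|mean(x) - mean(y)| divided by the (pooled, by default) sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("cohens_d needs at least 2 observations per sample")
    if denominator == "pooled":
        nx_, ny_ = x.size, y.size
        s2 = ((nx_ - 1) * np.var(x, ddof=1) + (ny_ - 1) * np.var(y, ddof=1)) / (nx_ + ny_ - 2)
        s = float(np.sqrt(s2))
    elif denominator == "control":
        s = float(np.std(y, ddof=1))
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if s == 0:
        raise ValidationError("zero standard deviation in Cohen's d")
    return abs(float(x.mean() - y.mean())) / s


def t_power(n: int, spec: PowerSpec) -> float:
    """Power of the t-test in ``spec`` at sample size n.

    Uses the noncentral-t distribution: for the one-sample family the
    noncentrality is d * sqrt(n) with df = n - 1; for the two-sample
    family (n per group) it is d * sqrt(n / 2) with df = 2n - 2.
    """
    if n < 2:
        raise ValidationError("t_power needs n >= 2")
    d = spec.effect_size
    if spec.family == "one-sample-t":
        df = n - 1
        ncp = d * np.sqrt(n)
    else:
        df = 2 * n - 2
        ncp = d * np.sqrt(n / 2)
    if spec.sides == 2:
        tc = stats.t.ppf(1 - spec.alpha / 2, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tc, df, ncp))


def sample_size_t(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n with t_power(n, spec) >= the target power."""
    if spec.delta == 0:
        raise ValidationError("delta = 0: the target power is unreachable")
    n = 2
    while n <= n_max:
        if t_power(n, spec) >= spec.power:
            return n
        n += 1
    raise ValidationError(f"required sample size exceeds {n_max}")


def select_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha_normality: float = 0.05,
    n_mc: int = 10000,
    seed: int | None = 0,
) -> TestResult:
    """Normality-gated two-sample comparison.

    Both samples pass the Lilliefors test -> two-sided Student t-test
    with Cohen's d; otherwise the Mann-Whitney rank-sum test.  The
    returned ``test_name`` records which branch ran.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p_x = lilliefors_test(x, n_mc=n_mc, seed=seed)
    p_y = lilliefors_test(y, n_mc=n_mc, seed=None if seed is None else seed + 1)
    if p_x >= alpha_normality and p_y >= alpha_normality:
        return two_sample_t(x, y)
    return rank_sum_test(x, y)


# ---------------------------------------------------------------------------
# Assay formulas
# ---------------------------------------------------------------------------


def preference_index(n_a: int, n_b: int, n_total: int) -> float:
    """Two-choice preference index (N_A - N_B) / N_total in [-1, 1]."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if n_a < 0 or n_b < 0 or n_a + n_b > n_total:
        raise ValidationError("counts must be non-negative with n_a + n_b <= n_total")
    return (n_a - n_b) / n_total


def survival_ratio(n_adults: int, n_larvae: int) -> float:
    """Fraction of larvae that developed into adult flies."""
    if n_larvae < 1:
        raise ValidationError("n_larvae must be at least 1")
    if not 0 <= n_adults <= n_larvae:
        raise ValidationError("n_adults must lie in [0, n_larvae]")
    return n_adults / n_larvae


def mhc_rate(count: int, window_s: float) -> float:
    """Mouth-hook contractions per minute from a count in a time window."""
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return count * 60.0 / window_s
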