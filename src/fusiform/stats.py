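"""Statistical decision tree used throughout the analyses.

Normality is gated by a Lilliefors test (Kolmogorov-Smirnov distance against a
normal with parameters estimated from the sample). Because the classical KS
null does not apply when parameters are estimated, the null distribution of
the statistic is generated by Monte Carlo: for each replicate, draw a normal
sample of the same size, re-estimate its parameters, and recompute the
distance. Group comparisons then branch: parametric (Student's t-test for two
groups, one-way ANOVA with Tukey HSD post-hoc for more) when every group
passes the gate, nonparametric (Wilcoxon rank-sum, Kruskal-Wallis) otherwise.
Incidence comparisons between two proportions use an exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    branch: str = ""
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null)
# ---------------------------------------------------------------------------

def _ks_distance_normal(x: np.ndarray) -> float:
    """KS distance of x against Normal(mean(x), sd(x))."""
    x = np.sort(x)
    n = x.size
    sd = x.std(ddof=1)
    z = sps.norm.cdf((x - x.mean()) / sd)
    hi = np.arange(1, n + 1) / n - z
    lo = z - np.arange(0, n) / n
    return float(max(hi.max(), lo.max()))


def _ks_distance_normal_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise KS distances for a (replicates, n) matrix of samples."""
    x = np.sort(x, axis=1)
    n = x.shape[1]
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = sps.norm.cdf((x - x.mean(axis=1, keepdims=True)) / sd)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum((grid_hi - z).max(axis=1), (z - grid_lo).max(axis=1))


def lilliefors_null(n: int, n_mc: int = 10000, seed=None) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic for size n."""
    rng = np.random.default_rng(seed)
    return _ks_distance_normal_rows(rng.standard_normal((n_mc, n)))


def lilliefors_test(sample, n_mc: int = 10000, seed=None,
                    null: np.ndarray | None = None) -> TestResult:
    """Lilliefors test of composite normality with a Monte-Carlo null.

    ``null`` may carry a precomputed :func:`lilliefors_null` distribution for
    the same n (useful when testing many samples of equal size). The p-value
    uses the add-one rule p = (1 + #{D_null >= D}) / (1 + n_mc) so it is never
    exactly zero.
    """
    x = np.asarray(sample, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need n >= 5 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    d = _ks_distance_normal(x)
    if null is None:
        null = lilliefors_null(x.size, n_mc=n_mc, seed=seed)
    p = (1.0 + np.count_nonzero(null >= d)) / (1.0 + null.size)
    return TestResult(test="lilliefors_mc", statistic=d, p_value=float(p),
                      n=(x.size,), extra={"n_mc": int(null.size)})


# ---------------------------------------------------------------------------
# group comparisons with the normality gate
# ---------------------------------------------------------------------------

def compare_groups(groups, alpha: float = 0.05, n_mc: int = 2000,
                   seed=0) -> TestResult:
    """Compare >= 2 groups, branching on the per-group Lilliefors gate.

    All groups normal at ``alpha``: Student's t-test (2 groups) or one-way
    ANOVA with Tukey HSD post-hoc (>2). Otherwise: Wilcoxon rank-sum (2) or
    Kruskal-Wallis (>2). Requires n >= 5 per group so the gate is defined.
    The result records the branch taken and the per-group gate p-values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for a in arrays:
        if a.size < 5:
            raise ValueError("each group needs n >= 5")
    ns = tuple(a.size for a in arrays)
    root = np.random.SeedSequence(seed)
    nulls = {}
    gate_p = []
    for a, child in zip(arrays, root.spawn(len(arrays))):
        if a.size not in nulls:
            nulls[a.size] = lilliefors_null(a.size, n_mc=n_mc, seed=child)
        gate_p.append(lilliefors_test(a, null=nulls[a.size]).p_value)
    normal = all(p > alpha for p in gate_p)

    posthoc = None
    if normal:
        if len(arrays) == 2:
            stat, p = sps.ttest_ind(arrays[0], arrays[1])
            name = "t-test"
        else:
            stat, p = sps.f_oneway(*arrays)
            name = "one-way ANOVA"
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            values = np.concatenate(arrays)
            labels = np.concatenate([np.full(a.size, i)
                                     for i, a in enumerate(arrays)])
            tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
        branch = "parametric"
    else:
        if len(arrays) == 2:
            stat, p = sps.ranksums(arrays[0], arrays[1])
            name = "Wilcoxon rank-sum"
        else:
            stat, p = sps.kruskal(*arrays)
            name = "Kruskal-Wallis"
        branch = "nonparametric"
    return TestResult(test=name, statistic=float(stat), p_value=float(p),
                      n=ns, branch=branch, posthoc=posthoc,
                      extra={"lilliefors_p": gate_p, "alpha": alpha})


# ---------------------------------------------------------------------------
# incidence comparison
# ---------------------------------------------------------------------------

def _round_half_up(x: float, digits: int = 1) -> float:
    """Round half away from zero (11/21 -> 52.4, 5/16 -> 31.3)."""
    scale = 10 ** digits
    return float(np.floor(abs(x) * scale + 0.5) / scale * np.sign(x))


def binomial_incidence_test(k1: int, n1: int, k2: int, n2: int,
                            method: str = "fisher") -> TestResult:
    """Exact comparison of two incidences k1/n1 vs k2/n2.

    A one-sample binomial test between two *observed* proportions is
    underdetermined, so the default is Fisher's exact test on the 2x2 table;
    ``method='binomial'`` tests k1 of n1 against the rate k2/n2 (conditional
    reading). Incidences are reported as percentages rounded to one decimal.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    inc1 = _round_half_up(100.0 * k1 / n1)
    inc2 = _round_half_up(100.0 * k2 / n2)
    if method == "fisher":
        stat, p = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        name = "Fisher exact"
    elif method == "binomial":
        res = sps.binomtest(k1, n1, p=k2 / n2)
        stat, p = res.statistic, res.pvalue
        name = "binomial (conditional)"
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(test=name, statistic=float(stat), p_value=float(p),
                      n=(n1, n2),
                      extra={"incidence_pct": (inc1, inc2), "k": (k1, k2)})
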