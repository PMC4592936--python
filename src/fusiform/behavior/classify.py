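"""Gaussian-null tinnitus classification from gap-startle ratio changes.

Behavioral evidence of tinnitus is inferred from the per-frequency change in
gap startle ratio between testing phases, Delta = post - pre. The null
distribution of Delta is estimated from sham-exposed (control) mice by a
maximum-likelihood Gaussian fit (mu, sigma); a mouse is classified as tinnitus
when its Delta exceeds the threshold mu + 2*sigma at at least one tested
frequency (strict inequality).

The sign convention Delta = post - pre makes the gap-detection deficit of
tinnitus mice (an *increase* in gap startle ratio after exposure) positive,
consistent with a positive classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ..stats import binomial_incidence_test, lilliefors_test


def delta_ratios(ratio_table: pd.DataFrame, measure: str = "gap") -> pd.DataFrame:
    """Per-mouse, per-frequency ratio change Delta = post - pre.

    ``ratio_table`` is the tidy output of
    :class:`~fusiform.behavior.qc.StartleRatioPipeline`. Frequencies absent
    (NaN) in either phase yield no Delta.
    """
    df = ratio_table[ratio_table["measure"] == measure]
    wide = df.pivot_table(index=["mouse_id", "frequency_khz"], columns="phase",
                          values="ratio", dropna=False)
    for phase in ("pre", "post"):
        if phase not in wide.columns:
            wide[phase] = np.nan
    out = wide.reset_index()
    out["delta"] = out["post"] - out["pre"]
    return out[["mouse_id", "frequency_khz", "delta"]]


def delta_matrix(deltas: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy deltas to a (mouse x frequency) matrix with NaN for absent."""
    return deltas.pivot(index="mouse_id", columns="frequency_khz", values="delta")


def tinnitus_threshold(mu: float, sigma: float) -> float:
    """Classification threshold: the point 2 standard deviations above the mean."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return mu + 2.0 * sigma


@dataclass
class DeltaDistribution:
    """Control Delta gap-startle ratios with their fitted Gaussian null."""

    deltas: np.ndarray
    mu: float
    sigma: float
    n: int
    lilliefors_p: float | None = None
    degenerate: bool = False

    @property
    def threshold(self) -> float:
        return tinnitus_threshold(self.mu, self.sigma)

    def fraction_below_threshold(self) -> dict:
        """Empirical and analytic mass below the mu + 2*sigma threshold.

        The analytic value is Phi(2) ~= 0.977 by construction.
        """
        from scipy.stats import norm
        empirical = float(np.mean(self.deltas < self.threshold))
        return {"empirical": empirical, "fitted": float(norm.cdf(2.0))}


def fit_control_distribution(deltas, min_n: int = 10,
                             lilliefors_seed=None) -> DeltaDistribution:
    """Maximum-likelihood normal fit (sample mean, sample SD) to control deltas.

    NaNs are ignored. Degenerate (zero-variance) samples are flagged rather
    than rejected. Requires at least ``min_n`` finite deltas.
    """
    arr = np.asarray(deltas, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(f"need >= {min_n} control deltas, got {arr.size}")
    mu = float(np.mean(arr))
    degenerate = np.ptp(arr) == 0.0
    sigma = 0.0 if degenerate else float(np.std(arr))   # MLE (ddof=0)
    lp = None
    if not degenerate:
        lp = lilliefors_test(arr, n_mc=2000, seed=lilliefors_seed).p_value
    return DeltaDistribution(deltas=arr, mu=mu, sigma=sigma, n=arr.size,
                             lilliefors_p=lp, degenerate=degenerate)


@dataclass
class MouseClassification:
    mouse_id: str
    label: str                               # tinnitus | non_tinnitus | unclassifiable
    exceeding_frequencies: tuple = field(default_factory=tuple)
    max_delta: float = np.nan

    def __post_init__(self):
        if self.label == "tinnitus" and not self.exceeding_frequencies:
            raise ValueError("tinnitus label requires >= 1 exceeding frequency")


def classify_mouse(deltas_by_freq: dict, threshold: float,
                   mouse_id: str = "") -> MouseClassification:
    """Classify one mouse from its per-frequency deltas.

    Tinnitus iff Delta > threshold (strict) at >= 1 frequency; mice with no
    usable frequency are reported as unclassifiable, never silently dropped.
    """
    usable = {f: d for f, d in deltas_by_freq.items() if np.isfinite(d)}
    if not usable:
        return MouseClassification(mouse_id, "unclassifiable")
    exceeding = tuple(sorted(f for f, d in usable.items() if d > threshold))
    label = "tinnitus" if exceeding else "non_tinnitus"
    return MouseClassification(mouse_id, label, exceeding,
                               max_delta=float(max(usable.values())))


class TinnitusClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian-null threshold classifier over per-frequency Delta ratios.

    ``fit(X)`` estimates the null from control deltas (any array-like; NaNs
    ignored) and sets ``mu_``, ``sigma_``, ``threshold_ = mu_ + 2 sigma_``,
    ``n_`` and ``lilliefors_p_``. ``predict(X)`` takes a (n_mice, n_freq)
    matrix (NaN = frequency absent) and returns per-mouse labels.
    """

    classes_ = np.array(["non_tinnitus", "tinnitus"])

    def __init__(self, min_control_n: int = 10, lilliefors_seed: int = 0):
        self.min_control_n = min_control_n
        self.lilliefors_seed = lilliefors_seed

    def fit(self, X, y=None):
        dist = fit_control_distribution(X, min_n=self.min_control_n,
                                        lilliefors_seed=self.lilliefors_seed)
        self.null_ = dist
        self.mu_ = dist.mu
        self.sigma_ = dist.sigma
        self.threshold_ = dist.threshold
        self.n_ = dist.n
        self.lilliefors_p_ = dist.lilliefors_p
        return self

    def decision_function(self, X):
        """Max finite Delta minus threshold per mouse (NaN if none usable)."""
        check_is_fitted(self, "threshold_")
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        with np.errstate(all="ignore"):
            mx = np.nanmax(np.where(np.isfinite(arr), arr, -np.inf), axis=1)
        mx[~np.isfinite(mx)] = np.nan
        return mx - self.threshold_

    def predict(self, X):
        score = self.decision_function(X)
        out = np.where(score > 0, "tinnitus", "non_tinnitus").astype(object)
        out[~np.isfinite(score)] = "unclassifiable"
        return out

    def classify_table(self, deltas: pd.DataFrame) -> pd.DataFrame:
        """Detailed classification of a tidy delta table.

        Returns one row per mouse: label, exceeding_frequencies, max_delta.
        """
        check_is_fitted(self, "threshold_")
        rows = []
        for mouse_id, grp in deltas.groupby("mouse_id"):
            by_freq = dict(zip(grp["frequency_khz"], grp["delta"]))
            c = classify_mouse(by_freq, self.threshold_, mouse_id)
            rows.append((c.mouse_id, c.label,
                         ",".join(str(f) for f in c.exceeding_frequencies),
                         c.max_delta))
        return pd.DataFrame(rows, columns=["mouse_id", "label",
                                           "exceeding_frequencies", "max_delta"])


def threshold_sweep(deltas_a, deltas_b, lo: float = -1.0, hi: float = 1.0,
                    step: float = 0.02) -> pd.DataFrame:
    """Fraction of deltas above threshold in two groups, over a threshold grid.

    Thresholds run from ``hi`` down to ``lo`` in ``step`` decrements. Used to
    compare two Delta distributions against the diagonal: identical
    distributions put the curve on the identity line. The returned frame
    carries ``attrs['max_deviation']``, the largest |fraction_b - fraction_a|.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n = int(round((hi - lo) / step))
    thresholds = hi - step * np.arange(n + 1)
    fa = (a[None, :] > thresholds[:, None]).mean(axis=1)
    fb = (b[None, :] > thresholds[:, None]).mean(axis=1)
    out = pd.DataFrame({"threshold": thresholds, "fraction_above_a": fa,
                        "fraction_above_b": fb})
    out.attrs["max_deviation"] = float(np.max(np.abs(fb - fa)))
    return out


def compare_incidence(k1: int, n1: int, k2: int, n2: int, method: str = "fisher"):
    """Compare tinnitus incidence between two groups (exact test).

    Returns the stats module's result object; incidences are reported as
    percentages rounded to one decimal (e.g. 11/21 -> 52.4).
    """
    return binomial_incidence_test(k1, n1, k2, n2, method=method)
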