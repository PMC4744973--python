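"""Local similarity analysis with order randomization and sign-consistency.

The local similarity (LS) score between two normalized series is the
largest-magnitude run of products over a contiguous subinterval, scaled by
the series length: a correlation-like statistic in [-1, 1] that can pick up
associations confined to part of the data. For unit-variance rank normal
scores the bound |LS| <= 1 follows from Cauchy-Schwarz.

Because the samples here do not form a regular time series, the LS score's
dependence on sample order is noise, not signal. The wrapper therefore
re-evaluates every taxon-diazotroph LS score under many random sample
orders (one shared order per shuffle across all taxa, 1000 shuffles by
default) and reports the mean and dispersion; an association counts as
significant only when every shuffle yields the same sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "local_similarity",
    "lsa_randomized",
    "sign_proportion_test",
    "LsaResult",
    "LocalSimilarityAnalysis",
]


def _ls_batch(R: np.ndarray) -> np.ndarray:
    """Signed LS per column of a (time x series) product matrix.

    Kadane-style dynamic program run simultaneously for the positive and
    negative directions: P_i = max(0, P_{i-1} + r_i), N_i = max(0,
    N_{i-1} - r_i); the score is the larger of the two running maxima
    (negative sign if the negative run wins), divided by the series length.
    """
    t, k = R.shape
    P = np.zeros(k)
    N = np.zeros(k)
    maxP = np.zeros(k)
    maxN = np.zeros(k)
    for i in range(t):
        r = R[i]
        P = np.maximum(0.0, P + r)
        N = np.maximum(0.0, N - r)
        maxP = np.maximum(maxP, P)
        maxN = np.maximum(maxN, N)
    return np.where(maxP >= maxN, maxP, -maxN) / t


def local_similarity(scores_x, scores_y, max_delay: int = 0) -> float:
    """Signed LS score of two equal-length score vectors.

    With ``max_delay > 0`` the maximum is additionally taken over lag
    offsets up to ``max_delay`` in either direction (the aligned positions
    shrink with the lag; the divisor stays the full length n).
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score vectors must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need length >= 3")
    best = 0.0
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            prod = x[: n - d] * y[d:]
        else:
            prod = x[-d:] * y[: n + d]
        # _ls_batch divides by the aligned length; rescale to the full n
        ls = _ls_batch(prod[:, None])[0] * len(prod) / n
        if abs(ls) > abs(best):
            best = float(ls)
    return best


@dataclass
class LsaResult:
    """Per-taxon mean LS score against a diazotroph variable."""

    table: pd.DataFrame
    target: str
    n_shuffles: int

    @property
    def mean_ls(self) -> pd.Series:
        return self.table["mean_ls"]

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]

    def to_frame(self) -> pd.DataFrame:
        return self.table


class LocalSimilarityAnalysis(BaseEstimator):
    """Order-randomized LSA of every taxon against one target variable.

    ``fit(X, y)`` expects ``X`` as a samples x taxa matrix of rank normal
    scores and ``y`` as the scored target. For each of ``n_shuffles`` random
    sample orders (shared across taxa within a shuffle) the LS score of
    every taxon is computed; ``results_`` holds the per-taxon mean, sd and
    the all-same-sign significance flag.
    """

    def __init__(self, n_shuffles: int = 1000, seed: int | None = 0,
                 max_delay: int = 0, target: str = "proportion"):
        self.n_shuffles = n_shuffles
        self.seed = seed
        self.max_delay = max_delay
        self.target = target

    def fit(self, X, y):
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        y = np.asarray(y, dtype=float)
        if len(y) != len(Xdf):
            raise ValueError("target length does not match samples")
        S = Xdf.to_numpy(dtype=float)
        n, k = S.shape
        rng = np.random.default_rng(self.seed)
        scores = np.empty((self.n_shuffles, k))
        for s in range(self.n_shuffles):
            perm = rng.permutation(n)
            R = S[perm] * y[perm][:, None]
            if self.max_delay == 0:
                scores[s] = _ls_batch(R)
            else:
                scores[s] = [
                    local_similarity(S[perm, j], y[perm], self.max_delay)
                    for j in range(k)
                ]
        mean = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sig = (scores > 0).all(axis=0) | (scores < 0).all(axis=0)
        self.scores_ = scores
        self.results_ = pd.DataFrame(
            {"mean_ls": mean, "sd_ls": sd, "significant": sig,
             "n_shuffles": self.n_shuffles, "target": self.target},
            index=Xdf.columns.rename("taxon_id"),
        )
        return self

    def result_(self) -> LsaResult:
        return LsaResult(self.results_, self.target, self.n_shuffles)


def lsa_randomized(ambient_scores, target_values, n_shuffles: int = 1000,
                   seed: int | None = 0, target: str = "proportion") -> LsaResult:
    """Mean/sd LS score of each taxon over shared random sample orders."""
    est = LocalSimilarityAnalysis(n_shuffles=n_shuffles, seed=seed, target=target)
    est.fit(ambient_scores, target_values)
    return est.result_()


def sign_proportion_test(k_positive: int, n_significant: int) -> float:
    """Two-sided 1-sample proportion test of p = 0.5 with continuity correction.

    z = (|k - n/2| - 0.5) / sqrt(n / 4); the continuity correction is
    clamped at exact balance so k = n/2 gives p = 1.
    """
    k, n = k_positive, n_significant
    if n < 1:
        raise ValueError("n_significant must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k_positive must lie in [0, n_significant]")
    z = max(abs(k - n / 2) - 0.5, 0.0) / np.sqrt(n / 4)
    return float(2 * norm.sf(z))
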