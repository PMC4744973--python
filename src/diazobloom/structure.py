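"""Functional / phylogenetic convergence of taxon-diazotroph associations.

Taxa that respond alike to diazotroph blooms may be clustered in trait
space or in the taxonomic hierarchy. The statistic is a weighted mean
pairwise distance (MPD): distances are Gower distances over binary traits
plus log cell size, or equal-height taxonomic-topology distances; weights
are pairwise cross products w_i * w_j of per-taxon weights derived from the
LS scores (rescaled to nonnegative by adding 1). A null distribution is
built by shuffling the LS scores across taxa, giving a standardized effect
size SES = (MPD_obs - null mean) / null sd. Negative SES means trait or
clade convergence among taxa positively associated with diazotrophs;
positive SES, convergence among the negatively associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.base import BaseEstimator

from .data import TaxonomyTable, TraitTable

__all__ = [
    "DistanceMatrix",
    "MpdSesResult",
    "gower_distances",
    "taxonomy_distances",
    "weighted_mpd",
    "ses_mpd",
    "SESMPD",
    "ls_class_anova",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative taxon-pair distances scaled to [0, 1]."""

    taxon_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1] or len(self.taxon_ids) != d.shape[0]:
            raise ValueError("distance matrix shape does not match taxon ids")
        finite = np.isfinite(d)
        if not np.allclose(d[finite], d.T[finite.T]):
            raise ValueError("distance matrix not symmetric")
        if np.nanmax(d) > 1 + 1e-9 or np.nanmin(d) < -1e-12:
            raise ValueError("distances must lie in [0, 1]")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("nonzero diagonal")
        self.d = d

    def subset(self, taxon_ids) -> "DistanceMatrix":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return DistanceMatrix(list(taxon_ids), self.d[np.ix_(idx, idx)])


def gower_distances(traits: TraitTable | pd.DataFrame) -> DistanceMatrix:
    """Gower distances over binary traits plus a quantitative log-size trait.

    Each pair's distance is the mean over its non-missing traits of the
    binary mismatch (0/1) and |delta log size| / range(log size). A pair
    with no shared non-missing trait gets a missing distance and a warning.
    """
    df = traits.data if isinstance(traits, TraitTable) else traits
    if len(df) < 2:
        raise ValueError("need >= 2 taxa")
    parts = []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if col == "size":
            lv = np.log(v)
            rng = np.nanmax(lv) - np.nanmin(lv)
            diff = np.abs(lv[:, None] - lv[None, :])
            parts.append(diff / rng if rng > 0 else np.zeros_like(diff))
        else:
            parts.append((v[:, None] != v[None, :]).astype(float)
                         + 0.0 * (v[:, None] + v[None, :]))  # NaN propagates
    stack = np.stack(parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = np.nanmean(stack, axis=0)
    if np.isnan(d).any():
        warnings.warn("taxon pair(s) with no shared traits: distance missing")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(df.index), d)


def taxonomy_distances(taxonomy: TaxonomyTable | pd.DataFrame, rank_list=None) -> DistanceMatrix:
    """Topology-only taxonomic distances on an equal-height ultrametric.

    d(a, b) = (index of the lowest shared rank) / (number of ranks), where
    index 0 is the same terminal taxon; taxa sharing no rank get d = 1 with
    a warning. Ranks are ordered lowest to highest.
    """
    df = taxonomy.data if isinstance(taxonomy, TaxonomyTable) else taxonomy
    ranks = list(df.columns) if rank_list is None else list(rank_list)
    k = len(df)
    m = len(ranks)
    lineages = df[ranks].to_numpy(dtype=object)
    out = np.ones((k, k))
    nohit = False
    for i in range(k):
        out[i, i] = 0.0
        for j in range(i + 1, k):
            level = m  # default: share nothing -> maximal depth
            for lvl in range(m):
                a, b = lineages[i, lvl], lineages[j, lvl]
                if pd.notna(a) and a == b:
                    level = lvl + 1
                    break
            else:
                nohit = True
            out[i, j] = out[j, i] = level / m
    if nohit:
        warnings.warn("taxon pair(s) sharing no rank: distance set to 1")
    return DistanceMatrix(list(df.index), out)


def weighted_mpd(dist: DistanceMatrix | np.ndarray, weights) -> float:
    """Cross-product weighted mean pairwise distance.

    MPD = sum_{i<j} w_i w_j d_ij / sum_{i<j} w_i w_j. Weights must be
    nonnegative with at least two strictly positive entries. Equal weights
    recover the unweighted MPD; any positive rescaling of the weights
    leaves the value unchanged.
    """
    D = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if (w > 0).sum() < 2:
        raise ValueError("need >= 2 strictly positive weights")
    num = 0.5 * (w @ np.nan_to_num(D) @ w)
    mask = ~np.isnan(D)
    np.fill_diagonal(mask, False)
    wprod = np.outer(w, w) * mask
    den = 0.5 * wprod.sum()
    return float(num / den)


@dataclass
class MpdSesResult:
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_low: float
    p_high: float
    n_null: int
    undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"observed": self.mpd_obs, "null_mean": self.null_mean,
              "null_sd": self.null_sd, "ses": self.ses,
              "p": min(self.p_low, self.p_high),
              "p_low": self.p_low, "p_high": self.p_high,
              "n_null": self.n_null, "undefined": self.undefined}]
        )


class SESMPD(BaseEstimator):
    """Standardized effect size of LS-weighted MPD against a label-shuffle null.

    Weights are ``ls + 1`` (rescaling LS in [-1, 1] to nonnegative, with a
    tiny positivity guard); the null permutes the LS scores across the taxa
    in the analysis set. ``p_low``/``p_high`` are the one-tailed proportions
    of null MPDs at or below / at or above the observed value.
    """

    def __init__(self, n_null: int = 9999, seed: int | None = 0):
        self.n_null = n_null
        self.seed = seed

    def fit(self, dist, ls_scores):
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        D = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
        ls = np.asarray(ls_scores, dtype=float)
        if len(ls) != D.shape[0]:
            raise ValueError("ls_scores not aligned to distance matrix")
        w = ls + 1.0 + 1e-9
        obs = weighted_mpd(D, w)
        rng = np.random.default_rng(self.seed)
        # vectorized over nulls: MPD = w'Dw / ((sum w)^2 - sum w^2)
        W = np.empty((self.n_null, len(w)))
        for i in range(self.n_null):
            W[i] = rng.permutation(w)
        Dz = np.nan_to_num(D)
        num = np.einsum("ni,ij,nj->n", W, Dz, W)
        den = W.sum(axis=1) ** 2 - (W**2).sum(axis=1)
        null = num / den
        self.mpd_obs_ = obs
        self.null_mean_ = float(null.mean())
        self.null_sd_ = float(null.std(ddof=1))
        self.undefined_ = self.null_sd_ <= 1e-12 * max(1.0, abs(self.null_mean_))
        self.ses_ = (
            float("nan") if self.undefined_ else (obs - self.null_mean_) / self.null_sd_
        )
        self.p_low_ = (1 + int((null <= obs).sum())) / (1 + self.n_null)
        self.p_high_ = (1 + int((null >= obs).sum())) / (1 + self.n_null)
        return self

    def result_(self) -> MpdSesResult:
        return MpdSesResult(
            self.mpd_obs_, self.null_mean_, self.null_sd_, self.ses_,
            self.p_low_, self.p_high_, self.n_null, self.undefined_,
        )


def ses_mpd(dist, ls_scores, n_null: int = 9999, seed: int | None = 0) -> MpdSesResult:
    est = SESMPD(n_null=n_null, seed=seed)
    est.fit(dist, ls_scores)
    return est.result_()


def ls_class_anova(mean_ls, classes, min_class_size: int = 2):
    """One-way ANOVA of mean LS scores across algal classes.

    Classes with fewer than ``min_class_size`` taxa are dropped. Returns
    (F, df_between, df_within, p).
    """
    s = pd.Series(np.asarray(mean_ls, dtype=float), index=None)
    cls = pd.Series(np.asarray(classes, dtype=object))
    groups = [g.to_numpy() for _, g in s.groupby(cls.values) if len(g) >= min_class_size]
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with enough taxa")
    f, p = f_oneway(*groups)
    df_b = len(groups) - 1
    df_w = sum(len(g) for g in groups) - len(groups)
    return float(f), df_b, df_w, float(p)
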