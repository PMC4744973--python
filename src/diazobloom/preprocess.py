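"""Sample/taxon filtering, diazotroph partitioning and score transformations.

The analysis pipeline separates the community into a diazotroph component
(heterocystous filamentous cyanobacteria of the genera *Aphanizomenon*,
*Nodularia*, *Dolichospermum* and *Anabaenopsis*) and the ambient,
non-diazotrophic remainder. Bloom intensity is the per-sample proportion of
diazotroph biomass in total wet-weight biomass; it is the predictor of every
downstream analysis.

Two transformations live here because several modules share them:

* Wisconsin double standardization after a square-root transform (species
  divided by their maxima, then samples by their totals) — the ordination
  pre-processing.
* Rank normal scores (van der Waerden scores at r/(n+1), average ranks for
  ties, rescaled to unit sample variance) — the local-similarity
  normalization. The unit-variance rescaling guarantees |LS| <= 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CommunityMatrix, SampleTable

__all__ = [
    "DIAZOTROPH_GENERA",
    "DEFAULT_SEASON_RULES",
    "DiazotrophPartition",
    "filter_samples",
    "partition_diazotrophs",
    "filter_rare_taxa",
    "standardize_community",
    "rank_normal_scores",
    "rank_normal_matrix",
    "WisconsinStandardizer",
    "RankNormalScorer",
]

logger = logging.getLogger("diazobloom")

#: Heterocyst-possessing genera counted as diazotrophs.
DIAZOTROPH_GENERA = ("Aphanizomenon", "Nodularia", "Dolichospermum", "Anabaenopsis")

#: Basin -> (first, last) month of the summer bloom window. Southern Baltic
#: Proper: July-September; northern basins and the Gulfs of Finland and
#: Riga: August-September.
DEFAULT_SEASON_RULES = {"BP": (7, 9), "GOF": (8, 9), "GOR": (8, 9)}

#: Year window used for the community analyses (two decades with a stable
#: compositional regime).
DEFAULT_YEAR_WINDOW = (1994, 2004)


def filter_samples(
    samples: SampleTable,
    season_rules: dict | None = None,
    year_window: tuple[int, int] | None = None,
    max_depth: float | None = None,
) -> pd.Index:
    """Select summer surface-mixed-layer samples by basin-specific windows.

    Parameters
    ----------
    samples : SampleTable
    season_rules : mapping basin -> (first_month, last_month), inclusive.
    year_window : optional (first_year, last_year), inclusive.
    max_depth : optional surface-layer rule; keeps samples whose ``depth``
        column (if present) is <= this value.

    Returns
    -------
    pandas.Index of surviving sample ids, in table order.
    """
    rules = dict(DEFAULT_SEASON_RULES if season_rules is None else season_rules)
    df = samples.data
    unknown = sorted(set(df["basin"].dropna()) - set(rules))
    if unknown:
        raise ValueError(
            f"unknown basin label(s) {unknown}; permitted: {sorted(rules)}"
        )
    month = df["date"].dt.month
    keep = pd.Series(False, index=df.index)
    for basin, (m0, m1) in rules.items():
        in_basin = df["basin"] == basin
        keep |= in_basin & (month >= m0) & (month <= m1)
    if year_window is not None:
        year = df["date"].dt.year
        keep &= (year >= year_window[0]) & (year <= year_window[1])
    if max_depth is not None and "depth" in df.columns:
        keep &= df["depth"].fillna(0.0) <= max_depth
    return df.index[keep]


@dataclass
class DiazotrophPartition:
    """Per-sample diazotroph biomasses/proportions and the ambient matrix.

    ``table`` columns: b_total, b_nod, b_aph (diazotroph biomasses) and
    p_total, p_nod, p_aph (proportions of total community biomass, in
    [0, 1] with p_nod + p_aph <= p_total).
    """

    table: pd.DataFrame
    ambient: CommunityMatrix
    diazotroph_taxa: list[str]

    @property
    def p_total(self) -> pd.Series:
        return self.table["p_total"]

    @property
    def p_nod(self) -> pd.Series:
        return self.table["p_nod"]

    @property
    def p_aph(self) -> pd.Series:
        return self.table["p_aph"]

    def proportion(self, which: str = "total") -> pd.Series:
        return self.table[f"p_{_species_key(which)}"]

    def biomass(self, which: str = "total") -> pd.Series:
        return self.table[f"b_{_species_key(which)}"]

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _species_key(which: str) -> str:
    key = {"total": "total", "nodularia": "nod", "nod": "nod",
           "aphanizomenon": "aph", "aph": "aph"}.get(which.lower())
    if key is None:
        raise ValueError(f"unknown diazotroph group {which!r}")
    return key


def _genus_of(taxon_id: str) -> str:
    return str(taxon_id).split()[0].split("_")[0].lower()


def partition_diazotrophs(
    community: CommunityMatrix,
    genus_list=DIAZOTROPH_GENERA,
    taxonomy=None,
) -> DiazotrophPartition:
    """Split the community into diazotroph and ambient components.

    Genus membership is matched case-insensitively against the leading
    genus token of the taxon id, or against the ``genus`` rank of the
    taxonomy lineage when one is supplied.
    """
    if not len(genus_list):
        raise ValueError("genus_list must be nonempty")
    genera = {g.lower() for g in genus_list}

    def is_member(taxon, targets) -> bool:
        if taxonomy is not None and taxon in taxonomy.taxon_ids and "genus" in taxonomy.ranks:
            g = taxonomy.data.loc[taxon, "genus"]
            if pd.notna(g) and str(g).lower() in targets:
                return True
        return _genus_of(taxon) in targets

    taxa = list(community.taxon_ids)
    diazo = [t for t in taxa if is_member(t, genera)]
    nod = [t for t in taxa if is_member(t, {"nodularia"})]
    aph = [t for t in taxa if is_member(t, {"aphanizomenon"})]
    if not diazo:
        warnings.warn("no taxa matched the diazotroph genus list; proportions all zero")

    df = community.data
    total = df.sum(axis=1)
    b_total = df[diazo].sum(axis=1) if diazo else pd.Series(0.0, index=df.index)
    b_nod = df[nod].sum(axis=1) if nod else pd.Series(0.0, index=df.index)
    b_aph = df[aph].sum(axis=1) if aph else pd.Series(0.0, index=df.index)

    zero = total <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} sample(s) with zero total biomass; proportion set to 0")
    denom = total.where(~zero, 1.0)
    table = pd.DataFrame(
        {
            "b_total": b_total,
            "b_nod": b_nod,
            "b_aph": b_aph,
            "p_total": (b_total / denom).where(~zero, 0.0),
            "p_nod": (b_nod / denom).where(~zero, 0.0),
            "p_aph": (b_aph / denom).where(~zero, 0.0),
        }
    )
    ambient = community.subset_taxa([t for t in taxa if t not in set(diazo)])
    return DiazotrophPartition(table=table, ambient=ambient, diazotroph_taxa=diazo)


def filter_rare_taxa(community: CommunityMatrix, min_samples: int) -> CommunityMatrix:
    """Drop taxa occurring (biomass > 0) in fewer than ``min_samples`` samples.

    Column order of the surviving taxa is preserved. The ordination default
    is ``min_samples=4`` (taxa present in three or fewer samples excluded);
    the local-similarity screen uses 10 per basin.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    occ = (community.data > 0).sum(axis=0)
    keep = [t for t in community.taxon_ids if occ[t] >= min_samples]
    if not keep:
        raise ValueError(
            f"no taxa occur in >= {min_samples} samples; lower the threshold"
        )
    return community.subset_taxa(keep)


def standardize_community(community: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Square-root transform followed by Wisconsin double standardization.

    Values are square-rooted, each taxon column is divided by its maximum,
    then each sample row by its total, so every nonempty row sums to one.
    All-zero rows are left as zeros with a warning (filter first).
    """
    df = community.data if isinstance(community, CommunityMatrix) else community
    out = np.sqrt(df.to_numpy(dtype=float))
    colmax = out.max(axis=0)
    if (colmax == 0).any():
        raise ValueError("all-zero taxon columns present; apply filter_rare_taxa first")
    out = out / colmax
    rowsum = out.sum(axis=1, keepdims=True)
    empty = rowsum[:, 0] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} all-zero sample row(s) left as zeros")
        rowsum[empty] = 1.0
    out = out / rowsum
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def rank_normal_scores(values) -> np.ndarray:
    """Rank normal (van der Waerden) scores rescaled to unit sample variance.

    Ranks (ties to average rank) are mapped through the standard normal
    quantile at r/(n+1), then divided by the sample standard deviation of
    the mapped values. Scores are invariant under strictly monotone
    transforms of the input and sum to ~0. A constant input returns all
    zeros (flagged with a warning).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D array")
    if v.size < 3 or not np.isfinite(v).all():
        raise ValueError("need >= 3 finite values")
    ranks = rankdata(v, method="average")
    scores = ndtri(ranks / (v.size + 1))
    sd = scores.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate input: all values identical; scores set to 0")
        return np.zeros_like(scores)
    return scores / sd


def rank_normal_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise rank normal scores of a samples x taxa table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {c: rank_normal_scores(df[c].to_numpy()) for c in df.columns}
    return pd.DataFrame(out, index=df.index)


class WisconsinStandardizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying sqrt + Wisconsin standardization.

    Stateless: ``fit`` only validates, ``transform`` standardizes the data
    it is given (the standardization is defined per-matrix, not per-column
    of a training set).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("negative abundances")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        return standardize_community(df).to_numpy()


class RankNormalScorer(TransformerMixin, BaseEstimator):
    """Column-wise rank normal score transformer (unit sample variance).

    Like the Wisconsin transformer this is a per-matrix normalization:
    ranks are recomputed on whatever matrix is transformed.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        return rank_normal_matrix(df).to_numpy()
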