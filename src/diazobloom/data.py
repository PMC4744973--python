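"""Domain types, table readers/writers and dataset bundling.

The central object is the :class:`CommunityMatrix` — a wide samples x taxa
table of nonnegative wet-weight biomass concentrations (ug L^-1 equivalent).
It is accompanied by a per-sample environment table, an optional binary +
size trait table and an optional ranked-lineage taxonomy table. All tables
travel as plain delimited text (comma by default, tab via ``sep``), UTF-8,
"." decimal, with missing values written as ``NA`` and accepted as ``NA`` or
an empty field. Dates are ISO-8601.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SampleTable",
    "TraitTable",
    "TaxonomyTable",
    "Dataset",
    "ValidationError",
    "load_dataset",
    "write_results",
    "taxonomy_to_newick",
]

logger = logging.getLogger("diazobloom")

_NA_VALUES = ["", "NA"]


class ValidationError(ValueError):
    """An input table violates one of the documented invariants."""


@dataclass
class CommunityMatrix:
    """Samples x taxa nonnegative biomass table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id. Entries are
        wet-weight biomass concentrations; missing values are treated as
        structural zeros (absence).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("community matrix needs >= 1 sample and >= 1 taxon")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        neg = np.argwhere(np.nan_to_num(values) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative biomass at sample {df.index[i]!r}, taxon {df.columns[j]!r}: "
                f"{values[i, j]}"
            )
        if np.isnan(values).any():
            df = df.fillna(0.0)
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def biomass(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[list(sample_ids)])

    def subset_taxa(self, taxon_ids: Sequence) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[:, list(taxon_ids)])

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "CommunityMatrix":
        df = _read_table(path, sep=sep)
        if df.columns.size < 2:
            raise ValidationError(
                f"{path}: community file needs a sample-id column plus >= 1 taxon column"
            )
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class SampleTable:
    """Per-sample space-time and chemistry metadata.

    Required columns: date, latitude, longitude, basin, and (possibly
    missing) temperature, salinity, dist_shore, chl_a, tn, tp. Extra
    covariate columns (irradiance, wind, ...) pass through untouched.
    Indexed by unique sample id; chl_a/tn/tp must be strictly positive
    where present.
    """

    data: pd.DataFrame

    _POSITIVE = ("chl_a", "tn", "tp")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in sample table: {dups}")
        if "date" in df.columns:
            df = df.assign(date=pd.to_datetime(df["date"], format="ISO8601"))
        for col in self._POSITIVE:
            if col in df.columns:
                bad = df.index[df[col].notna() & (df[col] <= 0)]
                if len(bad):
                    raise ValidationError(
                        f"{col} must be strictly positive where present; "
                        f"offending samples: {bad.tolist()[:5]}"
                    )
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def day_of_year(self) -> pd.Series:
        """Day-of-year derived from the stored calendar date."""
        return self.data["date"].dt.dayofyear.rename("day_of_year")

    def subset(self, sample_ids: Sequence) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)])

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "SampleTable":
        df = _read_table(path, sep=sep)
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.data.copy()
        if "date" in out.columns:
            out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class TraitTable:
    """Binary functional traits plus quantitative cell/colony size per taxon.

    Every non-``size`` column is binary (0/1/missing); ``size`` is a
    positive cell or colony volume where present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate taxon ids in trait table")
        for col in df.columns:
            if col == "size":
                bad = df.index[df[col].notna() & (df[col] <= 0)]
                if len(bad):
                    raise ValidationError(f"size must be > 0; offending taxa: {bad.tolist()[:5]}")
            else:
                vals = df[col].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValidationError(f"trait column {col!r} is not binary 0/1/missing")
        self.data = df

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.index

    @property
    def binary_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "size"]

    def subset(self, taxon_ids: Sequence) -> "TraitTable":
        return TraitTable(self.data.loc[list(taxon_ids)])

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "TraitTable":
        df = _read_table(path, sep=sep).set_index("taxon_id")
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class TaxonomyTable:
    """Ranked lineage labels per taxon, columns ordered lowest to highest rank."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate taxon ids in taxonomy table")
        empty = df.index[df.isna().all(axis=1)]
        if len(empty):
            raise ValidationError(f"taxa with empty lineage: {empty.tolist()[:5]}")
        self.data = df

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.index

    @property
    def ranks(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, taxon_ids: Sequence) -> "TaxonomyTable":
        return TaxonomyTable(self.data.loc[list(taxon_ids)])

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "TaxonomyTable":
        df = _read_table(path, sep=sep).set_index("taxon_id")
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class Dataset:
    """A referentially consistent bundle of community, sample and taxon tables."""

    community: CommunityMatrix
    samples: SampleTable
    traits: Optional[TraitTable] = None
    taxonomy: Optional[TaxonomyTable] = None
    ground_truth: Optional[object] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        common = self.community.sample_ids.intersection(self.samples.sample_ids)
        if len(common) == 0:
            raise ValidationError("community and sample table share no sample ids")
        only_comm = self.community.sample_ids.difference(common)
        only_samp = self.samples.sample_ids.difference(common)
        if len(only_comm) or len(only_samp):
            logger.warning(
                "dropping samples present in only one table: %s",
                only_comm.tolist() + only_samp.tolist(),
            )
        order = [s for s in self.community.sample_ids if s in set(common)]
        self.community = self.community.subset_samples(order)
        self.samples = self.samples.subset(order)

    @property
    def n_samples(self) -> int:
        return self.community.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.community.shape[1]

    def to_dir(self, path, sep: str = ",") -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.community.to_csv(path / "community.csv", sep=sep)
        self.samples.to_csv(path / "samples.csv", sep=sep)
        if self.traits is not None:
            self.traits.to_csv(path / "traits.csv", sep=sep)
        if self.taxonomy is not None:
            self.taxonomy.to_csv(path / "taxonomy.csv", sep=sep)

    @classmethod
    def from_dir(cls, path, sep: str = ",") -> "Dataset":
        path = Path(path)
        traits = path / "traits.csv"
        taxonomy = path / "taxonomy.csv"
        return load_dataset(
            path / "community.csv",
            path / "samples.csv",
            traits if traits.exists() else None,
            taxonomy if taxonomy.exists() else None,
            sep=sep,
        )


def _read_table(path, sep: str = ",") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValidationError(f"{path}: malformed delimited file: {exc}") from exc
    if df.columns.size == 0 or any(str(c).startswith("Unnamed") for c in df.columns[1:]):
        raise ValidationError(f"{path}: malformed header row (line 1)")
    return df


def load_dataset(
    community_path,
    samples_path,
    traits_path=None,
    taxonomy_path=None,
    sep: str = ",",
) -> Dataset:
    """Read and cross-validate a dataset from delimited text files.

    Samples present in only one of the community/sample tables are dropped
    with a logged warning; trait/taxonomy tables may cover a superset of the
    community's taxa.
    """
    community = CommunityMatrix.from_csv(community_path, sep=sep)
    samples = SampleTable.from_csv(samples_path, sep=sep)
    traits = TraitTable.from_csv(traits_path, sep=sep) if traits_path else None
    taxonomy = TaxonomyTable.from_csv(taxonomy_path, sep=sep) if taxonomy_path else None
    return Dataset(community, samples, traits=traits, taxonomy=taxonomy)


def write_results(result, path, format: str = "csv", *, seed=None, n_perm=None) -> None:
    """Serialize any result object to delimited text with a provenance header.

    ``result`` may be a DataFrame, a dataclass-like object exposing
    ``to_frame()``, or a plain mapping. The header comment records the seed
    and permutation count used (when given) and the package version.
    """
    from . import __version__

    sep = {"csv": ",", "tsv": "\t"}[format]
    if hasattr(result, "to_frame"):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result
    elif isinstance(result, dict):
        frame = pd.DataFrame([result])
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# diazobloom {__version__}; seed={seed}; n_perm={n_perm}\n")
        frame.to_csv(fh, sep=sep, na_rep="NA", index=frame.index.name is not None)


def taxonomy_to_newick(taxonomy: TaxonomyTable) -> str:
    """Equal-height ultrametric dendrogram of the ranked lineages, as Newick.

    Branch lengths step down 1/n_ranks per rank so that two taxa coalesce at
    the depth of their lowest shared rank, matching the taxonomy distance.
    """
    ranks = taxonomy.ranks
    m = len(ranks)
    step = 1.0 / m

    def subtree(taxa: pd.DataFrame, col: int) -> tuple[str, float]:
        """(newick without parent edge, root height) for a clade of taxa.

        A split over ranks[col] merges at the height of the next shared
        rank, (col + 2) / m; distinct taxa sharing the lowest rank merge at
        1 / m.
        """
        if len(taxa) == 1:
            return _quote(taxa.index[0]), 0.0
        if col < 0:
            inner = ",".join(f"{_quote(t)}:{step:.6g}" for t in taxa.index)
            return f"({inner})", step
        groups = list(taxa.groupby(ranks[col], dropna=False, sort=True))
        if len(groups) == 1:
            return subtree(groups[0][1], col - 1)
        h = min((col + 2) * step, 1.0)
        children = []
        for _, group in groups:
            s_child, h_child = subtree(group, col - 1)
            children.append(f"{s_child}:{h - h_child:.6g}")
        return "(" + ",".join(children) + ")", h

    body, height = subtree(taxonomy.data, m - 1)
    if not body.startswith("("):
        body = f"({body})"
    return f"{body};"


def _quote(label) -> str:
    s = str(label).replace(" ", "_")
    return s
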