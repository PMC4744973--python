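"""Synthetic plankton community generator with planted, recorded ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes — not bloom dynamics or biogeochemistry:

* strongly right-skewed diazotroph proportions (Beta laws; total proportion
  mean ~0.17, *Nodularia* far more skewed than *Aphanizomenon*),
* log-normal ambient taxon biomasses with per-taxon occupancy,
* per-basin summer sampling (Baltic Proper July-September, Gulfs of Finland
  and Riga August-September) over 1994-2004,
* temperature / salinity / distance-to-shore fields tilted so the planted
  *Nodularia* - *Aphanizomenon* weighted-mean offsets hold in expectation,
* chlorophyll generated so the z-scored log(Chl/TP) has a planted linear
  slope on the arcsine-sqrt diazotroph proportion plus a smooth spatial
  surface plus noise (and analogously for log(Chl/TN)),
* ambient taxa tilted toward/against the diazotroph proportion by planted
  per-taxon association strengths,
* optional trait / clade convergence among the positively associated taxa.

Every planted parameter is recorded in :class:`GroundTruth`; the same seed
and parameters always reproduce the identical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .data import CommunityMatrix, Dataset, SampleTable, TaxonomyTable, TraitTable

__all__ = ["SimulationParams", "GroundTruth", "generate_dataset", "make_worked_fixture"]

_BASIN_GEO = {
    # (lat, lon, salinity) centres of the three bloom basins
    "GOF": (59.7, 24.8, 5.5),
    "GOR": (57.8, 23.5, 5.2),
    "BP": (57.0, 19.5, 7.0),
}

_CLASSES = [
    "Bacillariophyceae",
    "Dinophyceae",
    "Cryptophyceae",
    "Chlorophyceae",
    "Chrysophyceae",
    "Prymnesiophyceae",
    "Cyanophyceae",
    "Euglenophyceae",
]

_CLASS_PHYLUM = {
    "Bacillariophyceae": ("Ochrophyta", "Chromista"),
    "Dinophyceae": ("Myzozoa", "Chromista"),
    "Cryptophyceae": ("Cryptophyta", "Chromista"),
    "Chlorophyceae": ("Chlorophyta", "Plantae"),
    "Chrysophyceae": ("Ochrophyta", "Chromista"),
    "Prymnesiophyceae": ("Haptophyta", "Chromista"),
    "Cyanophyceae": ("Cyanobacteria", "Bacteria"),
    "Euglenophyceae": ("Euglenozoa", "Protozoa"),
}

_TRAITS = [
    "pigment_chl_b",
    "pigment_fucoxanthin",
    "pigment_phycobilin",
    "autotrophy",
    "mixotrophy",
    "motility",
    "silica_uptake",
    "colony_formation",
]


@dataclass
class SimulationParams:
    """Generator settings; the defaults define the emulated study conditions."""

    n_samples: int = 600
    n_taxa: int = 60  # ambient (non-diazotroph) taxa
    basins: tuple = ("GOF", "GOR", "BP")
    year_window: tuple = (1994, 2004)
    # Right-skewed proportion laws (Beta); total mean 0.6/3.6 ~ 0.17
    beta_total: tuple = (0.6, 3.0)
    beta_nodularia: tuple = (0.25, 6.0)
    # Planted RUE slopes, on the z-score scale, against the arcsine-sqrt
    # transformed proportion of `rue_predictor`
    beta_p: float = 0.31
    beta_n: float = 0.15
    rue_predictor: str = "total"
    rue_noise_sd: float = 0.45
    # Planted Nodularia - Aphanizomenon weighted-mean niche offsets
    delta_t: float = 1.0      # deg C
    delta_s: float = 0.08     # salinity
    delta_d: float = 7.0      # km distance to shore
    # Planted ambient-taxon associations with the diazotroph proportion
    assoc_frac_pos: float = 0.3
    assoc_frac_neg: float = 0.3
    assoc_strength: tuple = (0.4, 0.9)  # |a| drawn uniform in this range
    biomass_noise_sd: float = 1.0
    # Trait / clade convergence among the top positively associated taxa
    convergence: bool = False
    convergence_quantile: float = 0.25


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset, for recovery tests."""

    beta_p: float
    beta_n: float
    rue_predictor: str
    delta_t: float
    delta_s: float
    delta_d: float
    assoc: pd.Series = field(repr=False)
    convergence_flag: bool = False
    convergence_taxa: tuple = ()
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)


def _asin_sqrt(p: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


def generate_dataset(params: Optional[SimulationParams] = None, seed: int = 0, **overrides) -> Dataset:
    """Draw a synthetic dataset; identical (params, seed) gives identical data."""
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = SimulationParams(**{**asdict_shallow(params), **overrides})
    rng = np.random.default_rng(seed)
    n = params.n_samples

    # --- space-time design -------------------------------------------------
    basins = np.array([params.basins[i % len(params.basins)] for i in range(n)])
    years = rng.integers(params.year_window[0], params.year_window[1] + 1, size=n)
    months = np.empty(n, dtype=int)
    for b in params.basins:
        m0, m1 = (7, 9) if b == "BP" else (8, 9)
        mask = basins == b
        months[mask] = rng.integers(m0, m1 + 1, size=mask.sum())
    days = rng.integers(1, 29, size=n)
    dates = pd.to_datetime(
        {"year": years, "month": months, "day": days}
    )
    lat = np.array([_BASIN_GEO[b][0] for b in basins]) + rng.normal(0, 0.4, n)
    lon = np.array([_BASIN_GEO[b][1] for b in basins]) + rng.normal(0, 0.8, n)

    # --- diazotroph proportions -------------------------------------------
    p_total = np.clip(rng.beta(*params.beta_total, size=n), 0.0, 0.95)
    p_nod = np.minimum(rng.beta(*params.beta_nodularia, size=n), p_total)
    rest = p_total - p_nod
    p_aph = 0.95 * rest
    p_doli = 0.05 * rest

    # --- environment with planted weighted-mean offsets --------------------
    # The niche contrast functional L(x) = sum(a_i x_i) with
    # a = p_nod/sum(p_nod) - p_aph/sum(p_aph) is the difference of the two
    # biomass-proportion-weighted means. Planting x = noise + c*v with
    # v = p_nod/mean - p_aph/mean and c = delta/L(v) makes the deterministic
    # part contribute exactly delta, leaving the noise part mean-zero (so a
    # zero delta yields a proper null, not a degenerate one).
    a_contrast = p_nod / p_nod.sum() - p_aph / p_aph.sum()
    v = p_nod / p_nod.mean() - p_aph / p_aph.mean()
    Lv = float(a_contrast @ v)
    if Lv <= 0:
        warnings.warn("degenerate niche-contrast direction; offsets not planted")
        Lv = 1.0

    def plant(base: np.ndarray, delta: float) -> np.ndarray:
        return base + (delta / Lv) * v

    temp = plant(16.3 + rng.normal(0, 1.3, n), params.delta_t)
    sal_base = np.array([_BASIN_GEO[b][2] for b in basins]) + rng.normal(0, 0.8, n)
    salinity = plant(sal_base, params.delta_s)
    dist = np.maximum(plant(np.exp(rng.normal(2.5, 0.7, n)), params.delta_d), 0.1)

    # --- nutrients and chlorophyll with planted RUE slopes ------------------
    log_tp = rng.normal(np.log(20.0), 0.4, n)
    p_pred = {"total": p_total, "nodularia": p_nod, "aphanizomenon": p_aph}[
        params.rue_predictor
    ]
    g = _asin_sqrt(p_pred)
    lat_c, lon_c = lat - lat.mean(), lon - lon.mean()
    spatial = 0.25 * lat_c + 0.15 * lon_c - 0.08 * lat_c**2 + 0.05 * lat_c * lon_c
    spatial -= spatial.mean()

    v_sp, v_g = spatial.var(), g.var()
    s2_eps = params.rue_noise_sd**2

    def raw_slope(beta: float, extra_var: float) -> float:
        # solve sd^2 = v_sp + (beta*sd)^2 v_g + s2 for the response sd so the
        # slope on the z-score scale is the requested beta
        denom = 1.0 - beta**2 * v_g
        if denom <= 0:
            warnings.warn(
                f"planted slope {beta} too large for the noise scale; left unscaled"
            )
            return beta
        sd = np.sqrt((v_sp + s2_eps + extra_var) / denom)
        return beta * sd

    eps = rng.normal(0, params.rue_noise_sd, n)
    b_raw_p = raw_slope(params.beta_p, 0.0)
    log_chl = log_tp - 1.9 + spatial + b_raw_p * g + eps

    s2_nu = 0.2**2
    nu = rng.normal(0, np.sqrt(s2_nu), n)
    b_raw_n = raw_slope(params.beta_n, s2_nu)
    # log(Chl/TN) = (log_chl - log_tp + 1.9 - log 15) + (b_raw_n - b_raw_p)*g ...
    log_tn = log_tp + np.log(15.0) + (b_raw_p - b_raw_n) * g + nu

    # --- ambient community with planted associations ------------------------
    k = params.n_taxa
    n_pos = int(round(params.assoc_frac_pos * k))
    n_neg = int(round(params.assoc_frac_neg * k))
    lo, hi = params.assoc_strength
    strengths = rng.uniform(lo, hi, size=k)
    signs = np.zeros(k)
    signs[:n_pos] = 1.0
    signs[n_pos : n_pos + n_neg] = -1.0
    assoc = signs * strengths

    taxon_ids = [f"Taxon{j + 1:03d} sp." for j in range(k)]
    z_g = (g - g.mean()) / g.std()
    mu = rng.normal(2.5, 1.2, size=k)
    log_b = (
        mu[None, :]
        + assoc[None, :] * z_g[:, None]
        + rng.normal(0, params.biomass_noise_sd, size=(n, k))
    )
    biomass = np.exp(log_b)
    occupancy = rng.uniform(0.55, 1.0, size=k)
    present = rng.random((n, k)) < occupancy[None, :]
    biomass = biomass * present

    amb_total = biomass.sum(axis=1)
    scale = amb_total / (1.0 - p_total)
    diazo = np.column_stack([p_nod * scale, p_aph * scale, p_doli * scale])

    columns = taxon_ids + [
        "Nodularia spumigena",
        "Aphanizomenon flosaquae",
        "Dolichospermum sp.",
    ]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    community = CommunityMatrix(
        pd.DataFrame(
            np.column_stack([biomass, diazo]),
            index=pd.Index(sample_ids, name="sample_id"),
            columns=columns,
        )
    )

    chl = np.exp(log_chl)
    samples = SampleTable(
        pd.DataFrame(
            {
                "date": dates.values,
                "latitude": lat,
                "longitude": lon,
                "basin": basins,
                "temperature": temp,
                "salinity": salinity,
                "dist_shore": dist,
                "chl_a": chl,
                "tn": np.exp(log_tn),
                "tp": np.exp(log_tp),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- traits and taxonomy ------------------------------------------------
    order_pos = np.argsort(assoc)[::-1]
    n_conv = max(2, int(round(params.convergence_quantile * k)))
    conv_taxa = tuple(taxon_ids[j] for j in order_pos[:n_conv]) if params.convergence else ()

    classes = [ _CLASSES[j % len(_CLASSES)] for j in rng.permutation(k) ]
    trait_rows, tax_rows = {}, {}
    for j, tid in enumerate(taxon_ids):
        binary = (rng.random(len(_TRAITS)) < 0.4).astype(float)
        cls = classes[j]
        if params.convergence and tid in conv_taxa:
            cls = "Chlorophyceae"
            binary[:3] = 1.0  # shared trait block
        phylum, kingdom = _CLASS_PHYLUM[cls]
        genus = tid.split()[0]
        if params.convergence and tid in conv_taxa:
            family, order = "ConvFam", "ConvOrd"
        else:
            family = f"{cls[:5]}Fam{rng.integers(1, 4)}"
            order = f"{cls[:5]}Ord{rng.integers(1, 3)}"
        trait_rows[tid] = list(binary) + [float(np.exp(rng.normal(6.0, 1.5)))]
        tax_rows[tid] = [genus, family, order, cls, phylum, kingdom]
    for tid, cls in [
        ("Nodularia spumigena", "Cyanophyceae"),
        ("Aphanizomenon flosaquae", "Cyanophyceae"),
        ("Dolichospermum sp.", "Cyanophyceae"),
    ]:
        phylum, kingdom = _CLASS_PHYLUM[cls]
        trait_rows[tid] = [0, 0, 1, 1, 0, 0, 0, 1, float(np.exp(rng.normal(8.0, 0.5)))]
        tax_rows[tid] = [tid.split()[0], "Nostocaceae", "Nostocales", cls, phylum, kingdom]

    traits = TraitTable(
        pd.DataFrame.from_dict(
            trait_rows, orient="index", columns=_TRAITS + ["size"]
        ).rename_axis("taxon_id")
    )
    taxonomy = TaxonomyTable(
        pd.DataFrame.from_dict(
            tax_rows,
            orient="index",
            columns=["genus", "family", "order", "class", "phylum", "kingdom"],
        ).rename_axis("taxon_id")
    )

    truth = GroundTruth(
        beta_p=params.beta_p,
        beta_n=params.beta_n,
        rue_predictor=params.rue_predictor,
        delta_t=params.delta_t,
        delta_s=params.delta_s,
        delta_d=params.delta_d,
        assoc=pd.Series(assoc, index=taxon_ids, name="assoc"),
        convergence_flag=params.convergence,
        convergence_taxa=conv_taxa,
        seed=seed,
        params=asdict_shallow(params),
    )
    return Dataset(community, samples, traits=traits, taxonomy=taxonomy, ground_truth=truth)


def asdict_shallow(params: SimulationParams) -> dict:
    return dict(asdict(params))


def make_worked_fixture() -> Dataset:
    """Tiny deterministic dataset with hand-checkable values.

    10 samples, 6 ambient taxa plus *Nodularia* and *Aphanizomenon*, integer
    biomasses. Used across the unit-test suite for hand-verified arithmetic
    (partition proportions, Wisconsin standardization, season filters).
    """
    sample_ids = [f"W{i + 1:02d}" for i in range(10)]
    taxa = [
        "Skeletonema marinoi",
        "Peridiniella catenata",
        "Teleaulax sp.",
        "Oocystis lacustris",
        "Chrysochromulina sp.",
        "Snowella lacustris",
        "Nodularia spumigena",
        "Aphanizomenon flosaquae",
    ]
    biomass = np.array(
        [
            #  Ske  Per  Tel  Ooc  Chr  Sno  Nod  Aph
            [4.0, 1.0, 0.0, 2.0, 0.0, 1.0, 1.0, 1.0],
            [9.0, 0.0, 1.0, 0.0, 2.0, 0.0, 0.0, 8.0],
            [1.0, 2.0, 3.0, 0.0, 0.0, 2.0, 2.0, 0.0],
            [0.0, 4.0, 1.0, 1.0, 1.0, 0.0, 0.0, 3.0],
            [2.0, 0.0, 2.0, 3.0, 0.0, 1.0, 6.0, 6.0],
            [3.0, 1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 4.0],
            [1.0, 0.0, 4.0, 2.0, 1.0, 2.0, 5.0, 5.0],
            [0.0, 2.0, 1.0, 0.0, 3.0, 1.0, 2.0, 1.0],
            [5.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 3.0],
            [2.0, 3.0, 2.0, 0.0, 1.0, 1.0, 4.0, 7.0],
        ]
    )
    community = CommunityMatrix(
        pd.DataFrame(biomass, index=pd.Index(sample_ids, name="sample_id"), columns=taxa)
    )
    dates = [
        "1995-08-10", "1996-08-20", "1997-09-05", "1998-06-15", "1999-08-01",
        "2000-07-15", "2001-09-10", "2002-08-25", "2003-07-20", "2004-09-01",
    ]
    basins = ["GOF", "GOF", "GOF", "GOF", "GOR", "GOR", "GOR", "BP", "BP", "BP"]
    samples = SampleTable(
        pd.DataFrame(
            {
                "date": dates,
                "latitude": [59.7, 59.8, 59.6, 59.9, 57.8, 57.7, 57.9, 57.0, 56.9, 57.1],
                "longitude": [24.8, 25.0, 24.5, 24.9, 23.5, 23.4, 23.6, 19.5, 19.4, 19.6],
                "basin": basins,
                "temperature": [16.0, 17.0, 15.5, 14.0, 18.0, 16.5, 17.5, 16.0, 15.0, 18.5],
                "salinity": [5.5, 5.6, 5.4, 5.7, 5.2, 5.1, 5.3, 7.0, 7.1, 6.9],
                "dist_shore": [5.0, 12.0, 8.0, 3.0, 15.0, 6.0, 20.0, 30.0, 10.0, 25.0],
                "chl_a": [2.0, 4.0, 1.5, 1.0, 5.0, 2.5, 6.0, 3.0, 1.8, 7.0],
                "tn": [300.0, 280.0, 320.0, 310.0, 260.0, 290.0, 250.0, 270.0, 305.0, 240.0],
                "tp": [2.0, 20.0, 18.0, 22.0, 15.0, 19.0, 14.0, 17.0, 21.0, 13.0],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    traits = TraitTable(
        pd.DataFrame(
            {
                "pigment_fucoxanthin": [1, 0, 0, 0, 1, 0, 0, 0],
                "motility": [0, 1, 1, 0, 1, 0, 0, 0],
                "silica_uptake": [1, 0, 0, 0, 0, 0, 0, 0],
                "colony_formation": [1, 1, 0, 1, 0, 1, 1, 1],
                "size": [800.0, 12000.0, 350.0, 1500.0, 90.0, 600.0, 50000.0, 40000.0],
            },
            index=pd.Index(taxa, name="taxon_id"),
        )
    )
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {
                "genus": ["Skeletonema", "Peridiniella", "Teleaulax", "Oocystis",
                          "Chrysochromulina", "Snowella", "Nodularia", "Aphanizomenon"],
                "family": ["Skeletonemataceae", "Gonyaulacaceae", "Teleaulacaceae",
                           "Oocystaceae", "Chrysochromulinaceae", "Merismopediaceae",
                           "Nostocaceae", "Nostocaceae"],
                "order": ["Thalassiosirales", "Gonyaulacales", "Pyrenomonadales",
                          "Chlorellales", "Prymnesiales", "Synechococcales",
                          "Nostocales", "Nostocales"],
                "class": ["Bacillariophyceae", "Dinophyceae", "Cryptophyceae",
                          "Chlorophyceae", "Prymnesiophyceae", "Cyanophyceae",
                          "Cyanophyceae", "Cyanophyceae"],
                "phylum": ["Ochrophyta", "Myzozoa", "Cryptophyta", "Chlorophyta",
                           "Haptophyta", "Cyanobacteria", "Cyanobacteria", "Cyanobacteria"],
                "kingdom": ["Chromista", "Chromista", "Chromista", "Plantae",
                            "Chromista", "Bacteria", "Bacteria", "Bacteria"],
            },
            index=pd.Index(taxa, name="taxon_id"),
        )
    )
    return Dataset(community, samples, traits=traits, taxonomy=taxonomy)
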