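# diazobloom

Statistical toolkit for asking how blooms of diazotrophic (N₂-fixing,
heterocystous) cyanobacteria — in the Baltic Sea chiefly *Nodularia
spumigena* and *Aphanizomenon* sp. — relate to the ambient phytoplankton
community and to community-level resource use efficiency.

The package is aimed at plankton ecologists working with long-term
monitoring data: a wide samples × taxa biomass matrix, a per-sample
environment/chemistry table and optional trait and taxonomy tables. It
implements, with permutation inference throughout:

- **Diazotroph partitioning.** Bloom intensity is the per-sample proportion
  *p* of diazotroph biomass in total wet-weight biomass; the heterocystous
  genera (*Aphanizomenon*, *Nodularia*, *Dolichospermum*, *Anabaenopsis*)
  are split off and all downstream analyses run on the ambient remainder.
- **Resource use efficiency (RUE).** RUE_P = ln(Chl *a*/TP), RUE_N =
  ln(Chl *a*/TN), z-scored and regressed as
  `z(RUE) ~ s(lat, lon) + β · asin(√p)`, where the spatial smooth (a
  penalized thin-plate radial basis selected by GCV) absorbs the
  geographic pattern of nutrient limitation; β is the slope of interest
  and slopes for different predictors/responses are Wald-comparable.
- **Community ordination.** Square-root + Wisconsin double standardization,
  Bray–Curtis dissimilarity, NMDS with a-posteriori vector fitting of *p*
  (R², 999 permutations), (partial) constrained correspondence analysis
  (constrained inertia fraction), and PERMANOVA (McArdle–Anderson sums of
  squares, pseudo-F) for continuous covariates.
- **Local similarity analysis (LSA).** The signed maximal run of products
  of rank-normal-scored series over a contiguous subinterval, |LS| ≤ 1.
  Because monitoring samples are not a regular time series, every
  taxon–diazotroph LS score is averaged over 1000 random sample orders;
  an association is "significant" only when all shuffles agree in sign,
  and the balance of positive vs negative associations gets a 1-sample
  proportion test with continuity correction.
- **Trait / phylogeny convergence.** Gower distances over binary traits +
  log cell size, or equal-height taxonomic-topology distances; the mean
  pairwise distance weighted by cross products of (LS + 1) is compared to
  a shuffle-the-LS-labels null, giving a standardized effect size (SES;
  SES < −2 ⇒ convergence among positively associated taxa).
- **Niche separation.** Biomass(-proportion)-weighted means of
  temperature, salinity, distance to shore or day of year for the two
  focal diazotrophs, with a within-sample swap null for the difference.
- **Synthetic data.** `generate_dataset` draws communities with the
  statistical structure the pipeline assumes (right-skewed Beta
  proportions, log-normal biomasses, per-basin summer sampling, planted
  RUE slopes, niche offsets, taxon associations and optional trait/clade
  convergence), recording every planted parameter in a `GroundTruth` so
  each stage can be tested end-to-end against known answers.

The analysis classes follow scikit-learn conventions (`fit`,
`get_params`/`set_params`, fitted attributes with a trailing underscore)
and the transformers compose with sklearn pipelines; module-level
functions (`fit_rue`, `permanova`, `lsa_randomized`, ...) are thin
wrappers over them.

## Worked example

```python
import diazobloom as db

ds = db.generate_dataset(seed=1, n_samples=600)
part = db.partition_diazotrophs(ds.community)
print(f"mean diazotroph proportion: {part.p_total.mean():.3f} "
      f"(Nodularia {part.p_nod.mean():.3f}, Aphanizomenon {part.p_aph.mean():.3f})")

rue = db.compute_rue(ds.samples)
s = ds.samples.data
fit = db.fit_rue(rue["z_rue_p"], part.p_total, s["latitude"], s["longitude"])
print(f"RUE_P slope: {fit.slope:.3f} +/- {fit.se:.3f} (p = {fit.p:.2g}, n = {fit.n})")

res = db.niche_shift_test(s["temperature"].to_numpy(),
                          part.p_nod.to_numpy(), part.p_aph.to_numpy(), seed=1)
print(f"temperature niche separation: {res.diff:.2f} degC (p = {res.p:.3f})")
```

prints

```
mean diazotroph proportion: 0.163 (Nodularia 0.025, Aphanizomenon 0.131)
RUE_P slope: 0.288 +/- 0.105 (p = 0.0061, n = 600)
temperature niche separation: 1.08 degC (p = 0.001)
```

The simulated community carries a mean bloom intensity of ~0.17; the RUE_P
slope of 0.288 ± 0.105 recovers the planted value of 0.31 (z-score units
per unit arcsine-√proportion), and the 1.08 °C *Nodularia*–*Aphanizomenon*
weighted-mean temperature difference recovers the planted 1 °C offset,
judged significant by the within-sample swap test.

The same analyses are available from a shell via the `diazobloom` console
script (`simulate`, `preprocess`, `rue`, `ordinate`, `lsa`, `structure`,
`niche`); see `diazobloom --help`.

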