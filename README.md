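# guildquant

Quantitative analysis of **ecological guilds** — sets of organisms exploiting
the same resource in the same way, regardless of phylogeny — from
gene-centric metagenomic profiles of nitrogen-cycle marker genes.  It is
aimed at microbial ecologists who have per-ORF annotated feature tables
(marker gene, taxon, sample, read count) from an oceanographic survey and
want to quantify not just *how abundant* each nitrogen function is, but
*how diversified* its sequence pool is relative to that abundance, and how
those quantities respond to depth and nutrient context.

## The model

For each marker gene, the number of distinct sequence variants *d* observed
in a (gene, taxon, context) stratum grows with the stratum's abundance *A*
(in globally normalized features per million, FPM) approximately as a power
law.  Fitting

> d_exp = c · A^γ

by least squares on log–log axes across all of a gene's strata gives the
richness *expected* from abundance alone.  The diversification statistic of
a stratum is

> δ = d_obs / d_exp

so δ = 1 (log δ = 0) means exactly the diversity expected from abundance,
δ < 1 an under-diversified guild, δ > 1 an over-diversified one.  The
guild-importance score **k = δ · A** rewards unexpected diversity and
penalizes its absence while retaining the abundance component; log k values
feed radial gene × taxon summaries.  Distributions of log δ across taxa are
compared between contexts with Gaussian-kernel density estimates, and
context effects are tested with a Gaussian-identity GLM fitted by IRLS,
rotated one-vs-rest so that each station class and each depth layer yields
a marginal contrast coefficient with a z-based p-value.

Upstream of the scores, the package purges false-positive marker calls
(paralogs) by resolving each query's phylogenetic placement to the smallest
labelled clade of a curated reference tree, and profiles each station's
N:P (NOx:PO4) vertical structure to flag water columns departing from the
cruise average.

Because real survey data are not bundled, a first-class synthetic-data
module generates cruises with known ground truth (power-law constants,
injected per-context δ multipliers, taxon turnover, N:P station shapes) so
the whole chain is testable end to end.

## Worked example

```python
import guildquant as gq

# a synthetic 11-station cruise with a 0.8 richness multiplier on the
# oxygen-minimum-zone station (an injected diversification deficit)
cfg = gq.SimulationConfig(seed=1, delta_multipliers={"OMZ": 0.8})
records, metadata, truth = gq.simulate_dataset(cfg)

strata = gq.aggregate_strata(
    gq.normalize_fpm(records), metadata, gq.station_class_map(cfg)
)
res = gq.RichnessAbundanceModel.from_strata(strata).fit()
scores = res.score()
print(gq.DeltaContrastModel.from_scores(scores).fit().summary())
```

```
One-vs-rest Gaussian-identity GLM contrasts of log_delta

context         axis     class          coef  std err      P>|z|  stars
NAtl            station  N_redox       0.074    0.009   7.09e-17  ****
NAtl            station  N_uptake      0.084    0.011   1.83e-14  ****
OMZ             station  N_redox      -0.228    0.008  2.28e-175  ****
OMZ             station  N_uptake     -0.207    0.010   3.06e-92  ****
...
mesopelagic     layer    N_uptake     -0.018    0.010     0.0763
```

The OMZ coefficients recover the injected effect: a multiplier of 0.8 on
expected richness implies a mean log δ shift of log 0.8 ≈ −0.223, and the
fitted OMZ-vs-rest contrasts are −0.228 (redox) and −0.207 (uptake), both
significant; uninjected layers sit near zero.  The same cruise's N:P
profiles flag the anomalous stations:

```python
flags = gq.flag_stations(gq.profiles_from_metadata(metadata))
# {'st120': 'low_np_anomaly', 'st141': 'high_np_anomaly'}
```

A `guildquant` CLI exposes the same steps as subcommands
(`simulate`, `validate`, `filter`, `abundance`, `npcontext`, `score`,
`density`, `glm`); see `guildquant --help`.

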