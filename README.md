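# ecoassembly

Null-model partitioning of microbial community assembly processes, with
attribution of each process to individual taxa (or taxonomic groups) and
to individual sampling units (or groups of samples).

Community ecologists routinely ask *which* forces structure a set of
microbial communities — deterministic selection or the stochastic trio
of dispersal limitation, homogenizing dispersal and drift — using the
two-step null-model framework built on phylogenetic and taxonomic
turnover. This package implements that framework and extends it with
two attribution layers: a taxon-removal analysis that asks which taxa a
classification actually hinges on, and a pair-counting analysis that
asks which sampling units carry each process.

## The model

For every pair of sites (k, m):

1. **Phylogenetic turnover.** The abundance-weighted beta mean nearest
   taxon distance

       βMNTD = ½ [ Σᵢ f_ik · min_{j∈m} d_ij + Σᵢ f_im · min_{j∈k} d_ij ]

   (f: within-site relative abundances, d: patristic distance) is
   standardized against a null that shuffles the tree's tip labels over
   the regional pool: SES.βMNTD = (obs − null mean)/null sd, 500
   randomizations by default. SES > 2 ⇒ heterogeneous selection,
   SES < −2 ⇒ homogeneous selection.
2. **Taxonomic turnover.** Remaining pairs get the Raup–Crick metric on
   Bray–Curtis, RC ∈ [−1, 1], from a null that preserves each site's
   richness and total abundance while drawing taxa ∝ occupancy and
   individuals ∝ pooled abundance. RC > 0.95 ⇒ dispersal limitation,
   RC < −0.95 ⇒ homogenizing dispersal, otherwise drift.

**Taxon (DTU) attribution**: each removal target (an ASV/OTU, or a whole
phylum/family) is masked from both communities of a pair and the metrics
are recomputed under the *identical* randomizations; five decision rules
attribute the pair to the process whose significance the removal
flipped. **Sampling-unit (DSU) attribution**: each unit's (or group's)
process profile is counted over the classified pairs that involve it.
A Mantel-correlogram gate (vegan conventions, 999 permutations) checks
for phylogenetic signal in niche differences before βMNTD inference.
A seeded simulator generates known-truth communities under all five
regimes for validation. See `docs/methods.md` for details, defaults and
known identifiability limits.

## Worked example

Simulate a community assembled by heterogeneous selection along an
environmental gradient (80 taxa, 12 sites) and classify it:

```python
from ecoassembly import AssemblyModel, SyntheticScenario, simulate_regime

scenario = SyntheticScenario("heterogeneous_selection", seed=1)
community, tree, metadata = simulate_regime(scenario)
model = AssemblyModel(community, tree, metadata=metadata)
result = model.fit(n_reps=500, seed=1)
print(result.summary())
```

```
Community assembly process classification
================================================
sites: 12    taxa (pool): 80
site pairs: 66    randomizations: 500    seed: 1
thresholds: |SES| > 2, |RC| > 0.95
------------------------------------------------
heterogeneous_selection       42  ( 63.6%)
homogeneous_selection          0  (  0.0%)
dispersal_limitation           6  (  9.1%)
homogenizing_dispersal         4  (  6.1%)
drift                         14  ( 21.2%)
------------------------------------------------
degenerate / unclassifiable pairs: 0
stochasticity (dispersal + drift): 36.4%
```

42 of 66 site pairs show phylogenetic turnover beyond the tip-shuffle
null (SES > 2): the simulated environmental filtering is recovered as
the dominant process, with about a third of pairs left to stochastic
processes. Group the sampling units by gradient band:

```python
print(result.attribute_sites(group_col="band").round(3).to_string(index=False))
```

```
target_id  n_sites  n_involved  n_evaluable  heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  drift  significant_fraction  stochasticity
     high        4          38           38                    0.658                    0.0                 0.132                   0.053  0.158                 0.842          0.342
      low        4          38           38                    0.763                    0.0                 0.026                   0.053  0.158                 0.842          0.237
      mid        4          38           38                    0.684                    0.0                 0.158                   0.000  0.158                 0.842          0.316
```

Each band is involved in 38 pairs; 84% of them carry a significant
signal, mostly heterogeneous selection — sites at the gradient extremes
(low, high) carry slightly more of it than mid-gradient sites.
`result.attribute_taxa(rank="family")` (with a taxonomy table) or
`result.attribute_taxa()` (per taxon) yields the removal-based
attribution table, one row per target, fractions summing to one.

The same pipeline runs from the shell:

```sh
ecoassembly simulate --regime drift --n-taxa 80 --n-sites 12 --seed 7 --out sim/
ecoassembly run-full --table sim/table.tsv --tree sim/tree.nwk \
    --metadata sim/metadata.tsv --group-col band --reps 500 --seed 7 --out results/
```

`run-full` writes `pair_metrics.tsv` (columns: site_a, site_b,
beta_mntd, null_mean, null_sd, ses, rc, process, status),
`attribution_taxa.tsv`, `attribution_sites.tsv`, optionally
`correlogram.tsv`, and a `manifest.json` recording seed, versions and
parameters; identical configurations give byte-identical outputs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline validation from scratch: it simulates
the heterogeneous-selection and drift recovery scenarios at the shipped
default sizes, classifies them, runs the divergent-taxon removal
attribution and grouped sampling-unit attribution, evaluates the
phylogenetic-signal gate on Brownian traits, prints a summary, and
writes the JSON result object to `--out`.
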