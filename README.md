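# metacap

Taxonomy-based prediction of gut-microbiota **metabolic capacity** from 16S
rRNA amplicon data, with the statistics to compare it between dietary
groups.

16S sequencing yields a table of amplicon sequence variants (ASVs) per
sample — who is there, not what they can do. When a collection of
genome-scale metabolic models (GSMMs) with taxonomic labels is available,
the reaction content of those models can stand in for function: each ASV is
matched to models by taxon-name equality at the lowest resolved rank
(species, then genus, then family; ASVs resolved only above family are
excluded), and for each mapped ASV *j* the expectation matrix entry

```
E(i, j) = (# matched models of j containing reaction i) / (# matched models of j)
```

is the frequency of occurrence of reaction *i* among its models. The
per-sample **normalized reaction abundance** is then the abundance-weighted
mean over mapped ASVs,

```
a_r(i) = Σ_j a_ASV(j) · E(i, j) / Σ_j a_ASV(j)
```

which lies in `[min_j E(i,j), max_j E(i,j)] ⊆ [0, 1]` and is invariant to
sequencing depth. Diets are compared reaction-by-reaction with two-sample
t-tests (pooled by default) under Benjamini–Hochberg correction (adjusted
p ≤ 0.05), and metabolic subsystems (pathways) are tested for
over-representation of significant reactions with one-sided Fisher's exact
tests, again BH-corrected. Ordination (PCA of reaction z-scores) and the
usual community summaries — core ASVs at a prevalence threshold, shared
ASVs between sample types, rarefaction, observed richness, Shannon's index,
Pielou's evenness, and Faith's phylogenetic diversity — round out the
toolkit.

The package is aimed at microbiome researchers who have an ASV table,
taxonomy assignments, and a reaction-annotated model catalog, and want a
tested, scriptable implementation of this pipeline. Because real model
collections are large external resources, `metacap` ships a first-class
synthetic-data generator (`SimulationConfig`, `generate_model_catalog`,
`generate_community`) that produces catalogs, taxonomies, trees, and
grouped Dirichlet–multinomial count tables **with an analytic ground
truth**, so every stage can be validated end to end.

## Worked example

```python
import metacap as mc

config = mc.SimulationConfig(seed=42)          # 6 diets x 13 digesta samples
catalog = mc.generate_model_catalog(config)
table, taxonomy, metadata, tree, truth = mc.generate_community(config, catalog)

matches = mc.match_all(taxonomy, catalog)
E = mc.build_expectation_matrix(matches, catalog)
abundances = mc.compute_reaction_abundances(table, E)
print(mc.mapping_summary(matches, E, abundances)["mapped_per_rank"])
```

prints

```
{'species': 6, 'genus': 30, 'family': 15}
```

— of the 60 simulated ASVs, 51 map to at least one model (6 at species
rank, 30 at genus, 15 at family; the remaining 9 are resolved above family
and excluded, mirroring how real mapped totals decompose by rank). Running
`python examples/predict_metabolic_capacity.py` continues this session: all
150 catalog reactions are present in every sample (gut communities share a
large metabolic backbone), and a PCA of the reaction z-scores reports
PC1 = 14.5% of variance with per-diet mean scores and 95% confidence
intervals. `examples/differential_pathways.py` plants a 3-fold shift of one
7%-abundance taxon and recovers it: 148 of 168 truly shifted reactions are
significant at BH 0.05, and 4 subsystems are enriched, each labelled with
the diet predicted to have the higher capacity.
`examples/community_diversity.py` shows the community summaries
(core ASVs, shared ASVs, rarefaction, alpha diversity).

A thin CLI mirrors the library for shell pipelines:

```bash
metacap simulate --seed 1 --out sim/
metacap map --taxonomy sim/taxonomy.tsv --catalog sim/catalog.json --out mapped/
metacap abundance --counts sim/counts.tsv --expectation mapped/expectation.tsv \
    --out abundance.tsv
metacap enrich --abundance abundance.tsv --metadata sim/metadata.tsv \
    --catalog sim/catalog.json --out enrichment/
```

Exit codes: 0 success, 2 malformed input file, 3 violated precondition.

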