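# holo

Holobiont community analysis toolkit: quantify how host genetic structure,
site and host size class shape associated symbiont and microbial
communities.

The package covers the full analysis chain at desk scale:

- **`holo.synthetic_data`** — ground-truth simulators: Balding–Nichols
  genotypes with a target FST, colony metadata with replicate structure
  (3 samples per large colony, 1 per small), Dirichlet-multinomial ASV
  count tables with planted cluster/site/size effects and optional
  intragenomic-variant ASV sets, and toy BLAST outfmt-6 hit tables.
- **`holo.host_genetics`** — analytic identity-by-state distances, clone
  pruning by average-linkage cut, cluster assignment, pairwise weighted
  Weir–Cockerham FST, and UPGMA trees (newick).
- **`holo.asv_processing`** — correlated-ASV grouping (phi > 0.8 on
  presence/absence, connected components), replicate aggregation,
  prevalence/read filters (≥3 colonies & >100 reads per ASV; >1000 reads
  & >3 nonzero ASVs per colony), Hellinger standardization, Bray–Curtis.
- **`holo.taxonomy_consensus`** — subtype calls from BLAST tabular hits:
  best 30 hits, e-value < 1e-100 and identity > 95, modal subtype
  assigned above 90% consensus (C15au → C15).
- **`holo.community_stats`** — PCoA (Gower centering, negative
  eigenvalues reported), marginal-term PERMANOVA with free label
  permutation (exhaustive enumeration supported), and a
  distance-to-centroid dispersion permutation test.
- **`holo.rda_forest`** — random forests of bootstrapped trees predicting
  PCoA axes from one-hot predictors; out-of-bag permutation importance
  weighted by OOB R² × eigenvalue share, summed per parent predictor and
  reported as relative shares.
- **`holo.pipeline`** — one-config orchestration with a reproducibility
  manifest (seeds, thresholds, output checksums).

## CLI

Everything is reachable through the `holo` command:

```sh
holo simulate --config sim.yaml --out data/ --seed 1
holo hostgen ibs --genotypes data/genotypes.tsv --out ibs.tsv
holo hostgen prune --dist ibs.tsv --out clones.tsv
holo hostgen clusters --dist ibs.tsv -k 5 --out clusters.tsv
holo hostgen fst --genotypes data/genotypes.tsv --clusters clusters.tsv --out fst.tsv
holo hostgen upgma --dist fst.tsv --out fst.nwk
holo community process --counts data/counts_community.tsv --meta data/metadata.tsv \
    --mode its2 --out community/
holo taxonomy --blast hits.tsv --out calls.tsv
holo stats permanova --dist community/braycurtis.tsv --meta colony_meta.tsv \
    --model "cluster + site + size_class" --out permanova.tsv
holo rdaforest --dist community/braycurtis.tsv --meta colony_meta.tsv \
    --predictors cluster,site,size_class --trees 1500 --axes 15 --seed 1 --out imp.tsv
holo run --config run.yaml          # full pipeline + manifest
```

`holo run` accepts a single YAML file; any omitted key falls back to
`holo.pipeline.DEFAULT_CONFIG`, which surfaces every analysis threshold
(correlation 0.8, e-value 1e-100, identity 95, consensus 0.90, 30 hits,
3 colonies, 100/1000 reads, 3 nonzero ASVs, 15 axes, 1500 trees).

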