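# netmarker

Network-topology biomarker prioritization from differential plasma
proteomics. The package implements, as a tested reusable pipeline, the
analysis chain used to turn two-dimensional-gel spot tables into a ranked
set of candidate predictive biomarkers:

1. **Differential spot filtering** (`netmarker.spots`) — one-way ANOVA on
   replicate intensities, fold change as a ratio ≥ 1 plus direction, and the
   retention rule *FC ≥ 1.5 and p < 0.05* (strict on p, non-strict on FC).
2. **PPI network construction and merging** (`netmarker.network`) — TSV/SIF
   edge-list ingestion with per-edge source provenance, identifier
   canonicalization through a user-supplied two-column map, union-merging,
   and a log–log power-law fit of the degree distribution.
3. **Hub-bottleneck selection** (`netmarker.centrality`) — degree and
   Brandes betweenness centrality (normalized per connected component);
   hubs at degree ≥ mean + 2·SD (sample SD; explicit overrides accepted),
   bottlenecks as the top 10% by betweenness (ceil count; ties broken by
   higher degree, then node id), hub-bottlenecks as the intersection, and a
   cross-network consensus restricted to the differentially expressed query
   proteins.
4. **Dense-module detection** (`netmarker.mcode`) — an MCODE-style
   algorithm (core-clustering-coefficient × k-core vertex weighting, greedy
   seeded expansion, 2-core haircut) with cluster score = density × size
   and a strict `> 4` score cutoff by default.
5. **Enrichment** (`netmarker.enrichment`) — one-sided hypergeometric
   (Fisher) over-representation against a GMT collection, or the more
   conservative variant computed with the overlap reduced by one; optional
   Benjamini–Hochberg adjustment.
6. **Group validation** (`netmarker.validation`) — one-way ANOVA and Tukey
   HSD simultaneous CIs, runnable from raw values *or* from printed
   summary statistics (mean, SD, n); the two routes agree exactly.
7. **Synthetic data** (`netmarker.synthetic`) — seeded generators for every
   input: log-normal spot tables with planted fold changes, scale-free
   networks with planted cliques/hubs, annotation collections with a
   planted enriched term, and zero-truncated Gaussian concentration groups.

A small plain-text demo dataset (differential spot records, merged-network
centrality table, module table, identifier map, and three-group plasma
summaries from a chronic-ITP drug-response study) ships inside the package
so the full pipeline runs offline; see `netmarker.datasets`.

## CLI

```sh
netmarker run-all                      # demo pipeline, writes netmarker_out/
netmarker run-all --config my.yaml --out-dir out/
netmarker simulate --kind spots --seed 1 --out spots.csv
netmarker spots --intensities spots.csv --out retained.tsv
netmarker network hprd.tsv string.tsv --id-map map.tsv --out merged.tsv
netmarker select merged.tsv --out selection.tsv
netmarker modules merged.tsv --out modules.tsv
netmarker enrich terms.gmt --query genes.txt --out enriched.tsv
netmarker validate --summary plasma.csv --out tukey.tsv
```

`run-all` executes spots → network → select → modules → enrich → validate
from a flat YAML config (defaults in `netmarker.pipeline.DEFAULTS`); stages
without configured inputs fall back to the bundled demo data, or are
skipped when `use_demo_fixtures: false`.

## Conventions and documented readings

- The spot-filter cutoff is read as |FC| ≥ 1.5 (the source's cutoff
  sentence contains an obvious typo) with strict p < 0.05.
- "Correlation rate" of a network is implemented as the Pearson r magnitude
  of the log–log degree-distribution fit (the statistic network-analysis
  tools report for the scale-free check).
- Betweenness is normalized per connected component, matching the values in
  the bundled centrality table.
- Tukey CI *midpoints* are the reproducible surface of the published
  three-group comparisons; the published CI half-widths imply a
  nonstandard studentized-range quantile (≈3.81 instead of q(0.05, 3, 23)
  ≈ 3.54) and are only checked for order of magnitude.
- The demo spot table's source reports significance only as "p < 0.05"; its
  `p_value` column therefore carries the documented placeholder upper bound
  0.049.
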