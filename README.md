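# soilscape

Landscape-scale spatial analysis of soil bacterial/archaeal communities:

- **`soilscape.synthetic`** — synthetic landscape generator: a 215 m square
  sampling grid with short-distance infill sites, Matérn-correlated Gaussian
  soil fields with target cross-correlations, spatially contiguous
  land-management clusters with exact per-cluster counts, and compositional
  taxon count tables (logistic-normal-multinomial forward model).
- **`soilscape.geostat`** — rank-space geostatistics: normal-scores transform
  and empirical back-transform, method-of-moments empirical variograms,
  Matérn variogram fitting by weighted least squares or maximum likelihood,
  effective ranges, global-neighbourhood ordinary kriging, and leave-one-out
  SSPE validation with simulation-based 95% confidence limits
  (chi-square(1) reference: mean 1, median 0.455).
- **`soilscape.community`** — rarefaction, taxonomy aggregation (including a
  phylum-level view that splits Proteobacteria into classes), weighted
  UniFrac, NMDS (Kruskal stress-1, best of restarts), soil PCA, and
  permutation-based environmental vector fitting.
- **`soilscape.pcnm`** — PCNM spatial eigenvectors (principal coordinates of a
  truncated neighbour matrix; auto-truncation at the longest MST edge).
- **`soilscape.varpart`** — collinearity pruning, forward selection under a
  double criterion (adjusted-R² gain with permutation p-value and decreasing
  AIC), three-block variance partitioning (soil / land management / space)
  by partial regression, and db-RDA on principal coordinates of an arbitrary
  dissimilarity matrix.
- **`soilscape.io` / `soilscape.pipeline` / `soilscape.cli`** — plain-text
  readers/writers (CSV/TSV/Newick), YAML config with a single master seed and
  deterministic per-stage child seeds, and the end-to-end runner.

## CLI

Every stage is a subcommand of the `soilscape` entry point:

```bash
# full synthetic pipeline (278 sites, 19 taxa) into a run directory
soilscape run --seed 1 --out runs/demo

# individual stages
soilscape simulate --seed 1 --out runs/demo
soilscape ordinate --table runs/demo/community.tsv --tree runs/demo/tree.nwk \
    --sites runs/demo/sites.csv --rarefy 10800 --permutations 999 --seed 1 \
    --out runs/demo
soilscape krige --sites runs/demo/sites.csv --value pH --method ml \
    --grid-step 50 --seed 1 --out runs/demo
soilscape validate --sites runs/demo/sites.csv --value pH --simulations 1000 \
    --run-dir runs/demo --seed 1
soilscape pcnm --sites runs/demo/sites.csv --out runs/demo/pcnm.csv
soilscape varpart --sites runs/demo/sites.csv --pcnm runs/demo/pcnm.csv \
    --taxa runs/demo/community.tsv --distance runs/demo/unifrac.tsv \
    --alpha 0.001 --permutations 999 --seed 1 --out runs/demo
```

A YAML config (`--config config.yaml`) can set every numeric default
(rarefaction depth 10,800; 999 permutations; 1,000 SSPE simulations;
alpha 0.001; vector-fit R² threshold 0.20) and toggle stages; the master
seed is mandatory and deterministically derives one child seed per stage.

## File formats

- site table: CSV with `site_id, x, y`, soil columns, `management`
- community table: TSV with `taxon`, `lineage` (semicolon-delimited ranks),
  then one column per site
- distance matrix: TSV, square, with identical id header row/column
- PCNM scores: CSV with `site_id, PCNM1..PCNMk`
- kriging surface: long-format CSV `x, y, prediction, kriging_variance`
  (predictions back-transformed to original units; variances in rank space)
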