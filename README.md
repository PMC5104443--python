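# foodnet

Analysis pipeline for bipartite country–product food production systems.
From long-format production, import and population tables it builds
binary and per-capita weighted country × product matrices and then:

- **Nestedness** — the NODF statistic over both sides of the bipartite
  graph, with significance against an ensemble of random networks of the
  same size and link count (empirical p-value and z-score).
- **Communities** — one-mode Gram projections, a Dice-type similarity
  matrix, and a descending-weight spanning forest whose edge-acceptance
  rule (at least one endpoint still isolated) splits the graph into
  disconnected sub-trees of strongly correlated countries or products.
- **Ranking** — the coupled non-linear fixed-point map producing a
  country fitness vector and a product specialization vector, with
  mean-one normalization, convergence diagnostics, per-year
  trajectories, and competition ranking.
- **Distributions** — empirical CCDFs, closed-form log-normal MLE, and
  a profile-likelihood three-parameter Weibull fit with
  parametric-bootstrap Kolmogorov–Smirnov goodness of fit.
- **Synthetic worlds** — a planted-capability generator (threshold rule
  plus flip noise, log-normal volumes) whose ground truth makes every
  downstream stage verifiable, and a fixed-link-count random generator
  used for the null ensembles.

## Command line

The `foodnet` entry point exposes `simulate`, `build`, `nestedness`,
`msf`, `fitness`, `fitdist` and `all`:

```sh
# generate a seeded synthetic world with planted ground truth
foodnet simulate --n-countries 40 --n-products 30 --noise 0.05 --seed 7 --outdir syn

# build one year's matrices (population filter: persons > 500,000)
foodnet build --production syn/production.csv --population syn/population.csv \
    --year 2011 --outdir out

# individual stages operate on the written panel
foodnet nestedness --matrix out/panel_2011_weighted.tsv --n-null 100 --seed 7
foodnet msf --matrix out/panel_2011_weighted.tsv --side country --outdir out
foodnet fitness --matrix out/panel_2011_weighted.tsv

# or run everything per year, emitting a manifest of artifacts
foodnet all --production syn/production.csv --population syn/population.csv \
    --seed 7 --outdir out
```

`all` also accepts a flat `key = value` config file via `--config`;
CLI flags override file entries, which override defaults. Every output
file carries the resolved config hash and seed in `#` header lines, so
reruns with an identical config are byte-identical. Exit codes: 0 ok,
1 usage error, 2 data error, 3 non-convergence under `--strict`.

## Layout

```
src/foodnet/
  tables.py         table parsing, filters, panel construction, TSV round trips
  synthetic.py      planted-capability and fixed-link random generators
  nestedness.py     degrees, overlap matrices, NODF, null significance
  projection.py     projections, similarity, spanning forest, import shares
  fitness.py        fixed-point map, ranking, trajectories
  distributions.py  CCDF, log-normal and three-parameter Weibull fits
  cli.py            command line, config, pipeline orchestration
```
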