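# rarelens

Rank-based comparison of large-scale search-query volume against registry
case counts, for epidemiological surveillance of rare diseases.

Rare diseases are individually scarce, hard to diagnose and chronically
under-registered, which makes classical survey epidemiology impractical.
Online search interest offers a cheap, real-time complementary signal:
patients (and their families) search for the diseases they live with.
`rarelens` implements a pipeline that

1. tallies per-disease query counts from a year-tagged query log using a
   keyword lexicon (disease names, synonyms, aliases; normalized substring
   matching),
2. converts them to **search popularity** p_{d,y} = q_{d,y}/Q_y and, via
   the population P_y, to **search-estimated patients**
   N̂_{d,y} = p_{d,y}·P_y,
3. ranks diseases annually by patient count in the search system and in a
   case registry, codes the **ranking difference** δ = r^S − r^C into
   three groups (RDG 0: δ < −τ, RDG 1: |δ| ≤ τ, RDG 2: δ > τ; τ = 20 by
   default), and summarises concordance (blocked Pearson correlation),
   stability (adjacent-year RDG intersections, top-k persistence) and the
   year/disease contributions to RDG via an effects-coded Gaussian GLM
   `RDG ~ C(year) + C(disease_group)`,
4. classifies each disease: **category 2** if it persistently ranks much
   higher in search than in the registry (publicity inflation and/or
   under-diagnosis — mine the searchers), **category 1** otherwise (the
   registry is relatively comprehensive — model patient numbers from it).

Because real search logs and national registry extracts are proprietary, a
seeded synthetic module generates study stand-ins with the assumed
structure (heavy-tailed prevalence, publicity spikes, Beta-distributed
under-reporting, background noise queries) together with noise-free
ground truth used as a test oracle.  See `docs/methods.md` for the model.

## Worked example

Run the whole study on the packaged default scenario (120 diseases,
2016–2019, seed 1):

```sh
rarelens run-all --seed 1 --out out/
```

or in Python:

```python
from rarelens import default_scenario
from rarelens.pipeline import run_pipeline

result = run_pipeline(default_scenario(seed=1), "out/")
print(result.rdg_counts)
```

The run writes `counts.csv`, `estimates.csv`, `ranks.csv`, `diffs.csv`,
`rdg_counts.csv`, `group_summary.csv`, `pearson.csv`, `intersections.csv`,
`topk.csv`, `glm.csv`, `classification.csv` plus `summary.json` and a
`run.log` under `out/`, with the emitted synthetic inputs in `out/inputs/`.
Key numbers from this exact run:

```
rdg   2016  2017  2018  2019
0       19    18    17    20
1       86    89    87    81
2       15    13    16    19
```

— per year, 81–89 of the 120 diseases (67.5–74.2 %) fall in RDG 1: the two
systems agree to within 20 rank positions for a clear majority, with the
remaining diseases split between the search-heavy (0) and registry-heavy
(2) tails.  The blocked Pearson correlations are 0.978–0.990, and the GLM
(`glm.csv`) shows the year/disease decomposition:

```
            term  coefficient  std_error       z     p
      year[2016]       -0.010      0.033  -0.319 0.749
      year[2017]       -0.019      0.033  -0.575 0.565
      year[2018]        0.015      0.033   0.447 0.655
      year[2019]        0.015      0.033   0.447 0.655
disease_group[0]       -0.620      0.037 -16.788 0.000
disease_group[1]       -0.051      0.028  -1.838 0.066
disease_group[2]        0.672      0.040  16.985 0.000
       intercept        1.028      0.025  41.331 0.000
```

Year effects are null (|z| < 0.6) while disease-group effects are large —
the relation between the two rankings is stable over time and dominated by
which group a disease sits in.  The classification (`classification.csv`)
assigns 104 diseases to category 1 and 16 to category 2.

Each stage is also exposed as its own subcommand on real files:

```sh
rarelens simulate --seed 1 --out data/
rarelens match --lexicon data/lexicon.json --log data/queries.tsv \
    --registry data/registry.csv --years 2016:2019 --out counts.csv
rarelens estimate --counts counts.csv --totals counts.totals.csv \
    --population data/population.csv --out estimates.csv
rarelens compare --estimates estimates.csv --counts counts.csv --out cmp/
rarelens glm --diffs cmp/diffs.csv --out glm.csv
rarelens classify --diffs cmp/diffs.csv --out classes.csv
```

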