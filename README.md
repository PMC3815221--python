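# aoalearn

Accumulator models of word learning. A word is acquired once a learner has
sampled a threshold number of relevant events from a process whose rate is a
power function of age; over a population of learners the age of acquisition
(AoA) then follows a generalized-gamma law. The package provides:

- **`aoalearn.models`** — closed-form CDF/pdf/hazard/mean/quantile for the
  four candidate AoA models (gamma = cumulative learning, Weibull =
  rate-change learning, Weibull-gamma = both, plus a logistic alternative),
  and qualitative hazard-shape classification.
- **`aoalearn.simulate`** — per-child acquisition-age simulation, synthetic
  checklist-style norms tables (654 words in 4 classes, 15 monthly
  proportions over ages 16–30 months, cohort of 1000) with known ground
  truth, and a well-separated model-selection benchmark.
- **`aoalearn.fit`** — per-word maximum-likelihood fitting (independent
  binomial cross-entropy over months, multistart bounded Nelder–Mead in log
  parameters) and BIC model selection (`BIC = -2L + k ln 15`).
- **`aoalearn.analyze`** — median AoA, best-model contingency tables with
  chi-square independence tests, parameter–attribute correlations with
  Fisher-z confidence intervals, and moving-average developmental trends
  (window of 20 words ranked by estimated mean AoA).
- **`aoalearn.io` / `aoalearn.cli`** — CSV formats with provenance headers
  and a command-line pipeline.

## Command line

```sh
# synthetic norms table + ground truth (654 words, cohort of 1000)
aoalearn simulate --seed 7 --out data/

# fit all four models per word; `select` additionally flags BIC winners
aoalearn fit data/norms.csv --out data/fits.csv
aoalearn select data/norms.csv --out data/fits.csv

# contingency tables, chi-square test, correlations, trend series
aoalearn analyze data/fits.csv --out data/summaries \
    --norms data/norms.csv --attributes data/attributes.csv --plots

# end-to-end synthetic pipeline with a selection-accuracy report
aoalearn demo --seed 7 --out demo/
```

`--n-words` subsamples the fixture for quick runs; a YAML file passed via
`--config` overrides any `FitConfig` field (cohort size, optimizer
tolerances, multistart grid, bounds).

Norms CSVs carry columns `word,class,p16..p30` with proportions in [0, 1];
attribute CSVs are long tables `word,attribute,value`. Every output starts
with `#` comment lines recording the package version, seed and a config
hash.

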