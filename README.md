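# welfagg

Herd-level lameness scoring, cumulative-link mixed ordinal modelling of
expert acceptability ratings, and a compensation analysis comparing the two
— with seeded synthetic-data generators so the whole pipeline is testable
without external data.

## What it does

- **`welfagg.scoring`** — per-cow gait scores (0 non-lame / 1 mildly lame /
  2 severely lame) → herd prevalences → a weighted 0–100 lameness index
  (mild weight 2, severe weight 7, normalized by the maximum weight) → a
  monotone shape-preserving piecewise-cubic welfare-score transform through
  configurable anchors → four-level categories, a nine-profile prevalence
  grid, and a configurable measures→criteria→principles→overall aggregation
  skeleton.
- **`welfagg.ordinal`** — from-scratch cumulative-link (mixed) models for
  0–10 ratings: logit link, equidistant thresholds θ_j = α + (j−1)δ, a
  normally distributed respondent intercept integrated out by Gauss–Hermite
  quadrature; ML fitting with deterministic multistarts, AIC selection over
  four fixed-effect structures, average-respondent prediction, acceptability
  binning (0–2 / 3–4 / 5–7 / 8–10, "acceptable" = rating ≥ 6), a
  dominance-violation panel-cleaning rule, and a per-measure random-effects
  agreement model.
- **`welfagg.synthetic_data`** — seeded generators for herds (multinomial
  gait scores at target prevalences), expert panels (cumulative-logit truth
  plus optional uniform-random contaminants), and per-measure validity
  ratings.
- **`welfagg.compensation`** — profile cross-tabulation at the three
  aggregation levels, predicted acceptability tables, Wilson confidence
  intervals, and the compensation report contrasting expert verdicts with
  aggregated categories.
- **`welfagg.case_study`** — the published 44-farm summary table (profile
  counts and row percentages), used for arithmetic-consistency checks.

## CLI

```bash
welfagg all --seed 1 --outdir out            # full pipeline, defaults
welfagg all --config myrun.yaml --outdir out # YAML/JSON config
```

Subcommands `simulate-herds`, `simulate-panel`, `score`,
`fit-acceptability`, `fit-agreement`, `compare` and `report` run the stages
individually against the CSV/JSON artifacts in the output directory
(`herds.csv`, `ratings.csv`, `measures.csv`, `scores.csv`, `fits.json`,
`agreement.csv`, `crosstab.csv`, `acceptability.csv`, `report.json`,
`report.md`, `manifest.json`). Identical seeds give byte-identical outputs.

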