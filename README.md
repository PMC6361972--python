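# emtscreen

Analysis pipeline for a dual-fluorescence co-culture cytotoxicity screen
that looks for compounds selectively killing EMT-like cells, plus the
downstream confirmation chain:

* **Plate normalization & QC** — per-well cell counts (13 fields, two
  channels) normalized to vehicle wells of the same plate; assay quality via
  Z'-factor, S/N and S/B on the positive-control channel.
* **Hit calling** — three-criterion selectivity rules on normalized green /
  red viabilities and their R/G ratio, classifying compounds as
  `emt_selective`, `epithelial_selective`, `pan_cytotoxic` or `inactive`.
* **Dose-response** — four-parameter logistic fitting on the log10 axis,
  relative EC50 and absolute IC50 (with range censoring), integer
  fold-selectivity, growth-rate-corrected GR metrics with GR50, and the
  cumulative population-doubling-level formula.
* **Panel classification & GSEA** — sensitive/resistant split at an
  absolute-IC50 cutoff (100 nM default) and a from-scratch gene set
  enrichment analysis (signal-to-noise ranking, weighted running-sum ES,
  phenotype-permutation null, NES, nominal p and FDR q).
* **Synthetic data** — seeded generators for plate counts (Poisson or
  negative-binomial), 4PL viability tables, exponential growth curves and
  expression matrices with a planted enriched gene set, so the whole
  pipeline runs without any external downloads.

## CLI

```bash
emtscreen all --outdir out/                 # full demo pipeline, seeded
emtscreen demo-config > config.yaml         # inspect / edit the config
emtscreen all --config config.yaml --outdir out/ --seed 7

emtscreen simulate  --config config.yaml --outdir sim/
emtscreen qc        --counts sim/counts.csv --layout sim/layouts.csv --out qc.csv
emtscreen call-hits --counts sim/counts.csv --layout sim/layouts.csv \
                    --out hits.csv --g-min 0.55 --r-max 0.41 --ratio-max 0.65
emtscreen fit-dr    --table sim/dose_response.csv --out fits.csv \
                    --selectivity-out selectivity.csv
emtscreen classify  --table fits.csv --cutoff 100 --out panel.csv
emtscreen gsea      --matrix sim/expression.tsv --phenotype sim/phenotype.txt \
                    --gmt sim/gene_sets.gmt --n-perm 1000 --out gsea.csv
```

`all` runs simulate → qc (with a Z' ≥ 0.5 plate gate) → call-hits → fit-dr
→ classify → gsea and writes a `manifest.json` carrying the seed, the
config hash and headline results; every output table starts with a comment
header recording the same. Reruns with the same config and seed are
byte-identical.

## File formats

Delimited text throughout (comma for `.csv`, tab otherwise): plate layouts
and per-field counts, dose-response and growth tables, a genes-by-samples
expression matrix with a one-line phenotype sidecar, and GMT gene sets.
Channel labels GFP/mCherry are normalized to green/red at parse time; well
addresses accept unpadded input ("A1") and normalize to "A01".
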