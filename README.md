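# mirbind

Two-stage miRNA target prediction in 3'-UTRs:

1. **Site stage (TS).** All canonical seed-match sites (6mer, 7mer-A1,
   7mer-m8, 8mer) are enumerated per (miRNA, UTR) pair and described by a
   154-dimensional feature registry spanning seven families — site type,
   duplex binding stability, site accessibility, 3'-supplementary pairing,
   conservation, SNP annotations, and sequence descriptors. A
   gradient-boosted classifier (missing values handled natively) scores each
   site with a *binding confidence*; features can be pruned by forward
   stepwise greedy selection maximizing cross-validated MCC.
2. **Transcript stage (TM).** Per-site probabilities are aggregated per
   (miRNA, gene) — sum plus the top three — and a second classifier scores
   the likelihood of functional repression (*interaction confidence*).
   Gene targets resolve to their longest annotated 3'-UTR.

Training data are assembled from verified site interactions (positives) and
candidate sites filtered against a validated-pair list, balanced 1:1 by
random under-sampling. Repression labels derive from relative expression
against an untransfected control (≤ 0.60 repressed, 1.00–1.10 unaffected,
everything else excluded).

A synthetic-data module (`mirbind.simulate`) generates complete corpora —
miRNAs, UTRs with implanted sites, conservation tracks, SNP tables,
validated-pair lists, expression tables, plus a ground-truth manifest — so
every stage is trainable and testable without downloads.

## CLI

A single executable with one subcommand per pipeline stage:

```bash
mirbind simulate --out corpus --n-mirnas 5 --n-transcripts 100 --seed 1
mirbind scan --corpus corpus --out scanned
mirbind evaluate --corpus corpus --sites scanned/sites.tsv --out eval
mirbind build-dataset --corpus corpus --out ds --seed 1
mirbind stats --dataset ds --out stats
mirbind select-features --dataset ds --out sel --seed 1 --k 10 --max-features 22
mirbind train-ts --dataset ds --out ts --seed 1
mirbind train-tm --corpus corpus --ts-model ts/ts_model.joblib --out tm --seed 1
mirbind predict --corpus corpus --ts-model ts/ts_model.joblib \
    --tm-model tm/tm_model.joblib --mirna syn-miR-1 --target GENE1 --out pred
```

Each command writes its outputs plus a `config.json` snapshot; exit codes
are 0 (success), 2 (input error), 3 (missing upstream artifact).
`predict` emits a per-pair interaction report and a per-site sub-table with
1-based inclusive coordinates, site types, and binding confidences.

## Layout

```
src/mirbind/
  sequence_io.py     FASTA/TSV readers and writers, ID resolution
  site_scanner.py    canonical seed-match enumeration and classification
  features/          registry, seven feature families, association tests
  datasets.py        negative filtering, under-sampling, labels, splits
  models/            metrics, TS classifier + greedy selection, TM aggregation
  simulate.py        synthetic corpora with ground-truth manifests
  cli.py             subcommand entry points
```
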