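# fitmeta

Tools for identifying FIT-dependent iron-homeostasis genes from
multi-line/multi-condition differential-expression comparisons in
*Arabidopsis thaliana*, and for ranking iron-deficiency marker genes by
cross-study consistency ("virtual dataset" meta-analysis).

## What it does

* **Ternary regulation calls** (`fitmeta.regulation`) — converts per-comparison
  tables of log2 fold change and p-value into calls in {-1, 0, +1}
  (defaults: p ≤ 0.05 and linear fold change ≥ 1.5, both inclusive), assembles
  them into gene × comparison matrices with a measured-gene mask, and computes
  regulated-gene sets and Venn partitions.
* **Sign-pattern cascades** (`fitmeta.cascades`) — four-step filters over the
  seven canonical contrasts of WT, the *fit* knock-out and the HA-FIT
  over-expressor at +Fe/-Fe. The *robust* cascades require the pattern in
  roots AND seedlings (contrasts 6, 2, 5, 1); the *tissue* cascades run in a
  single tissue (contrasts 6, 2, 5, 7) and subtract the robust set.
* **Virtual-dataset meta-analysis** (`fitmeta.virtual`) — per-gene ABS
  (occurrence count), SUM (signed call sum), RAT (|SUM|/ABS) and
  VIRT ((SUM/N)·RAT) across a compendium of studies, with direction-dependent
  denominators that exclude induced-only sources for down-regulated genes;
  threshold filtering (|SUM| ≥ 2, RAT ≥ 0.5, |VIRT| ≥ 0.25) and deterministic
  marker ranking. A published 25-gene × 14-analysis reference compendium is
  bundled (`fitmeta.datasets.load_marker_compendium`).
* **Marker-anchored clustering** (`fitmeta.clustering`) — hierarchical
  clustering of fold-change profiles (default: Pearson correlation distance,
  average linkage), extraction of clusters containing marker genes, and
  cross-dataset membership tallies.
* **Synthetic data** (`fitmeta.simulate`) — generators for comparison tables
  with planted FIT-dependence classes and for ternary study matrices with
  planted consistency levels, so the whole pipeline is testable offline.

## CLI

All stages are subcommands of a single entry point:

```bash
fitmeta simulate comparisons --n-genes 500 --seed 1 --out data/
fitmeta call --manifest data/roots_manifest.tsv --tables data/ --prefix roots_ \
    --out roots_calls.tsv --mask-out roots_mask.tsv
fitmeta filter-fit --roots roots_calls.tsv --roots-manifest data/roots_manifest.tsv \
    --seedlings seedlings_calls.tsv --seedlings-manifest data/seedlings_manifest.tsv \
    --mode robust-induced --out robust.tsv --summary-out robust.json
fitmeta simulate studies --n-genes 300 --consistency 0.9 --out studies/
fitmeta virtual --matrix studies/study_matrix.tsv --studies studies/study_manifest.tsv \
    --out virtual.tsv --summary-out virtual.json
fitmeta rank --matrix studies/study_matrix.tsv --studies studies/study_manifest.tsv \
    --direction up -k 5
fitmeta cluster --profiles profiles.tsv --maxclust 4 --out clusters.tsv
fitmeta run --seed 1 --out run/          # full synthetic pipeline + run manifest
```

All tabular I/O is headered, tab-separated, UTF-8 text. Logs go to stderr;
results only to files/stdout.

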