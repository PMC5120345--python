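# rakerid

Species identification of dried mobulid (devil ray / manta) gill rakers from
market surveys, combining two channels:

* **DNA barcoding** — Kimura 2-parameter (K2P) distances over aligned COI
  (761 bp) and NADH2 (1033 bp) sequences, neighbor-joining trees with
  bipartition-frequency bootstrap supports, monophyletic single-species
  cluster extraction, best-identity species assignment against a reference
  panel, and an intra-/inter-specific divergence ("barcoding gap") summary.
* **Morphology** — five-point filament-length protocol, a strict >70 mm
  Manta size screen, the three-step frontline enforcement rule (fused
  terminal lobes → variegated screen → finger-like projections), a
  transparent naive-Bayes classifier parameterised by the per-species trait
  frequency table, and a random-forest classifier with out-of-bag error and
  per-feature usefulness ranking.

A seeded synthetic generator emulates the five-species market mix
(103/25/27/12/21 specimens), per-species filament-length and price
distributions, categorical trait frequencies, and sequence panels with
intra-species divergence ≲1% and inter-species divergence ≳4%, providing
ground truth for every other module. Market reporting covers composition
percentages, count-weighted mean price, per-city prices and a linear
length→price fit.

## Layout

| module | contents |
| --- | --- |
| `rakerid.barcode_core` | FASTA I/O, transition/transversion tallies, K2P distances, distance matrices (PHYLIP + long CSV export) |
| `rakerid.tree_cluster` | neighbor joining, bootstrap supports, cluster extraction, identity assignment, gap summary |
| `rakerid.morphology` | specimen model, specimen CSV dialect, three-step rule, Bayes and random-forest classifiers |
| `rakerid.synthetic_data` | seeded generator of reference panels and specimen sets |
| `rakerid.market_report` | composition/price summaries, end-to-end pipeline, JSON report |
| `rakerid.profiles` | default per-species parameter tables |
| `rakerid.cli` | `rakerid` command-line interface |

## CLI

```bash
rakerid --seed 1 --out-dir survey simulate          # synthetic market survey
rakerid --out-dir out distance survey/references_COI.fasta
rakerid --seed 1 --out-dir out tree survey/queries_COI.fasta --replicates 100
rakerid gap survey/references_COI.fasta
rakerid classify survey/specimens.csv
rakerid market survey/specimens.csv
rakerid --seed 1 --out-dir out identify survey/specimens.csv \
    --refs-coi survey/references_COI.fasta \
    --queries-coi survey/queries_COI.fasta
```

`--config` accepts YAML/JSON or flat `key=value` files whose keys override
generator fields (see `rakerid.synthetic_data.GeneratorConfig`).

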