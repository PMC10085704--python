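# chromkit

Quantitative downstream analysis of chromatin-proteome ("chromatome")
experiments, starting from wide protein-group intensity matrices:

- **io_tables** — TSV intensity matrices, sample designs
  (fraction / condition / replicate), GMT annotation sets, self-describing
  result exports. Raw zeros become missing on import; all statistics run
  on the log2 scale.
- **synthetic_data** — seeded simulators with full ground truth: a
  six-fraction fractionation series (whole cell, cytoplasm, nuclei, three
  chromatin washes), paired chromatome/proteome matrices over multiple
  conditions, and pulldown-vs-IgG (ChIP-MS style) experiments with
  iBAQ-like values. Missingness is intensity-dependent (logistic MNAR).
- **preprocessing** — valid-value filtering (e.g. "at least 2 of 3"),
  CV-based QC (linear scale), and Gaussian-downshift imputation
  (width 0.2, downshift 1.8 column SDs by default).
- **differential_stats** — s0-moderated two-sample tests with
  permutation-based FDR, paired chromatome-minus-proteome contrasts,
  multi-group permutation ANOVA with a minimal fold-change filter, and
  Benjamini-Hochberg adjustment.
- **fraction_classification** — z-scored six-fraction profiles, k-means
  clustering with hierarchical centroid ordering, automatic cluster
  labelling, and the profile- or test-based high-confidence chromatome.
- **comparative_binding** — relative chromatin binding (chromatome log2
  minus mean proteome log2; positive = chromatin-enriched), RCB ANOVA +
  clustering, fold-change ranking, row normalization, Pearson correlation.
- **enrichment** — Fisher's exact annotation enrichment against the
  identified background with BH correction, and strict full-valid term
  counts.
- **chipms** — pulldown-vs-IgG differential enrichment and bait-normalized
  complex stoichiometry from iBAQ values.

## Command line

```bash
chromkit simulate --kind fraction --seed 7 --out sim/
chromkit qc       sim/matrix.tsv --design sim/design.tsv --out qc.tsv
chromkit impute   sim/matrix.tsv --design sim/design.tsv --seed 1 --out imputed.tsv
chromkit anova    imputed.tsv    --design sim/design.tsv --out anova.tsv
chromkit classify imputed.tsv    --design sim/design.tsv --out clusters/
chromkit diff     chromatome.tsv --design design.tsv \
    --group-a naive --group-b formative --out diff.tsv
chromkit relbind  chromatome.tsv proteome.tsv --design design.tsv --out rcb.tsv
chromkit enrich   foreground.txt background.txt annotations.gmt --out go.tsv
chromkit chipms   ibaq_matrix.tsv --design design.tsv \
    --bait BAIT --members SUBA,SUBB --out chip/
chromkit correlate a.tsv b.tsv --out r.json
```

Defaults of every operation can be overridden with a flat YAML config
passed as `--config`; `--seed` controls all randomness.

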