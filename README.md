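# bulgeselect

Analysis pipeline for single-step *in vitro* selections of
self-phosphorylating deoxyribozymes, built around a 47-nt catalytic core
with 14 variable positions (10 fully randomized, two base pairs encoded by
R-Y or Y-R degeneracy). The package covers:

- **`library_model`** — the degenerate library's genotype space: exact
  library size (67,108,864 for the default bulge spec), the fraction of
  genotypes able to form both encoded base pairs (56.25%), lexicographic
  enumeration, uniform sampling, and embedding/extraction of genotypes
  into/from the core sequence.
- **`read_processing`** — merged amplicon reads (FASTA/FASTQ) to a
  genotype count table: primer clipping, orientation against the reference
  scaffold, fixed-position matching, extraction of the 14 variable
  positions, and counts-per-million (CPM) normalization with full
  rejection accounting.
- **`selection_sim`** — a synthetic single-step selection: a ground-truth
  genotype-to-reaction-probability landscape per substrate (logistic link
  over additive/epistatic/pairing effects), enrichment proportional to the
  reacted fraction, and multinomial read sampling. Registered benchmark
  scenarios: `additive`, `epistatic`, `specificity-planted`,
  `imbalanced`.
- **`enrichment`** — two-arm comparison: inner merge on common genotypes,
  the log2 CPM-ratio specificity score, CPM distribution summaries, and
  top-sequence selection.
- **`mutation_effects`** — per-position stratification of specificity
  scores, effect-range ranking of positions, named-variant lookups, and a
  permutation null for calibration.
- **`ml_model`** — one-hot encoded genotype-to-CPM and
  genotype-to-specificity regression: seeded 80/20 split with nested
  downsampling, 3-fold cross-validated grid search, a feed-forward
  network (default 3x200 hidden units, alpha 0.001, batch 100, constant
  learning rate 0.01, early stopping, 200 iterations max),
  Spearman/R^2/MAE evaluation, learning curves, and single-position /
  base-pair mean-effect baselines.
- **`cli`** — pipeline orchestration with deterministic per-stage seed
  derivation.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the exact
combinatorial quantities and the substituted synthetic-benchmark
properties (parameter recovery, baseline comparisons, skew diagnostics,
mutation-effect recovery) end to end.

## CLI

```bash
# generate a synthetic benchmark selection (two arms + ground truth)
bulgeselect simulate --scenario specificity-planted --seed 7 --out sim/ --fastq

# process merged reads into a count table
bulgeselect process-reads --in sim/arm_A.fastq --spec sim/spec.yaml --arm 4-MUP --out armA.tsv

# merge two arms and compute specificity scores
bulgeselect enrich --arm-a sim/arm_A.tsv --arm-b sim/arm_B.tsv --out merged.tsv

# rank positions by specificity effect
bulgeselect mutscan --merged merged.tsv --out effects.tsv

# train the network on CPM or score targets
bulgeselect train --task score --merged merged.tsv --out run/

# or run the whole pipeline from one config
bulgeselect run --config config.yaml
bulgeselect report --run <output_dir>
```

## Notes

- Coordinates are 1-based over the 47-nt core.
- The study's core sequence is not public; the packaged reference scaffold
  is a configurable placeholder, and every numeric result above is
  independent of the fixed bases.
- The specificity score is log base 2 of cpm_a / cpm_b; arm-exclusive
  genotypes are excluded from score tables (a display-only pseudocount is
  used for scatter exports).
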