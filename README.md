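# comention

Semi-supervised ensemble classification and confidence-ranked retrieval of
sentence-level protein–phenotype co-mentions.

A *co-mention* is a sentence that names both a protein and a phenotype
(e.g. an HPO term). Such a sentence may or may not express a real
biological relationship, so a classifier is needed to separate *good*
(valid) from *bad* (invalid) co-mentions. This package implements the full
pipeline:

1. **extraction** — sentence splitting and dictionary-based entity matching
   over a document corpus, emitting one co-mention record per
   (sentence, protein id, phenotype id) pair;
2. **preprocessing** — entity masking (`PROT`/`PHENO` sentinels),
   tokenization, vocabulary building, fixed-length integer encoding, and a
   stratified 60/20/20 train/validation/test split;
3. **models** — a classifier contract with three built-in implementations
   (a pure-NumPy CNN, a pure-NumPy bidirectional RNN, and a fast linear
   "lightweight" model), plus a probability-averaging ensemble; a
   pretrained transformer can be plugged in at runtime behind the same
   contract (`register_base_classifier`) but is never required;
4. **selftrain** — the semi-supervised loop: fit a base classifier on the
   small labeled set, score the unlabeled pool, select k confident
   pseudo-labels (threshold-then-sample, class-ratio preserving) with k
   tunable by validation F1, and train the final CNN+RNN ensemble on the
   expanded set;
5. **evaluation** — precision/recall/F1, rank-statistic AUROC, repeated
   hold-out (same split, varying seeds) and paired t-tests;
6. **ranking** — a curation-assistant store answering protein / phenotype /
   pair queries with top-k sentences by descending ensemble confidence;
7. **synthetic** — a template-based generator of lexicons, corpora and
   labeled/unlabeled datasets with tunable signal strength and label
   noise, so everything is testable offline.

## CLI

Everything is reachable through one entry point; every command writes a
`*.manifest.json` with input/output digests and resolved seeds.

```bash
# generate a synthetic workspace
comention simulate --outdir work --seed 1

# end-to-end: self-train an ensemble, evaluate, score and query
comention selftrain --train work/labeled.tsv --val work/test.tsv \
    --pool work/unlabeled.tsv --proteins work/proteins.tsv \
    --phenotypes work/phenotypes.tsv --k 2000 \
    --out work/model.json --report work/report.json --seed 1
comention evaluate --model work/model.json --test work/test.tsv \
    --proteins work/proteins.tsv --phenotypes work/phenotypes.tsv \
    --out work/eval.json
comention score --in work/unlabeled.tsv --model work/model.json \
    --proteins work/proteins.tsv --phenotypes work/phenotypes.tsv \
    --out work/scored.tsv
comention rank --store work/scored.tsv --protein SP0001 --phenotype SH0002 --top-k 5
```

Other commands: `extract`, `preprocess`, `train`, `compare`. Pass
`--k auto` to `selftrain` to tune the added size over the configured
candidates by validation F1. Flat YAML config files can override any
preprocessing/training/self-training default (see the dataclasses in
`comention.preprocessing`, `comention.models`, `comention.selftrain`).

## File formats

- corpus: JSON-lines (`doc_id`, optional `year`, `text`) or plain text,
  one document per line;
- lexicons: 2-column TSV `entity_id<TAB>surface_name`, one row per name;
  phenotype ids are validated against `HP:\d{7}` when requested;
- co-mentions: 12-column TSV (doc id, sentence index, sentence, protein
  id/span, phenotype id/span, year, label, confidence) with empty strings
  for absent values; tabs/newlines inside sentences are escaped so the
  round trip is exact;
- models: a single self-contained JSON archive (weights + vocabulary +
  preprocessing config).
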