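# painlex

Mining contemporary pain descriptors from social-media text and revising a
multidimensional pain questionnaire.

The package implements a two-round text-mining workflow over social-media
posts:

1. **Preliminary round** — posts are cleaned (usernames, URLs, symbol runs
   removed), kept when the token `pain` and a target descriptor lie within a
   configurable hop limit of each other on the post's word graph, scored for
   sarcasm (posts rated strictly above 0.7 on [0,1] are dropped), and fed to
   a seeded skip-gram-with-negative-sampling embedding. Up to 20 positively
   similar words per keyword are extracted, pruned by three exclusion rules
   (contrasting meaning, shared root stem, configured stoplist), and tagged
   by provenance (original keywords vs thesaurus-derived keywords vs both).
2. **Final round** — the expanded keyword list plus a pain-condition
   requirement filters a second corpus; per-descriptor post counts and mean
   emotion-derived pain intensities then drive the questionnaire revision:
   a bottom-decile prevalence threshold, rule-tagged removals, placement of
   qualifying new words into their assigned subclasses, a new psychological
   subclass, and a stable intensity-based reordering of every subclass.

Because the original 2019 corpus is not distributable, the package ships a
first-class synthetic corpus generator (`painlex.synthetic_corpus`) with
planted association strengths, sarcasm rates, condition mentions, and
analytic count expectations, so the whole pipeline is testable end to end
offline. A machine-readable fixture of the published original-vs-suggested
questionnaire comparison is bundled and exactly reproduced by the revision
engine.

## CLI

All stages are subcommands of `painlex` (or `python -m painlex.cli`):

```bash
painlex simulate --config config.yaml --out posts.jsonl --labels-out labels.jsonl
painlex clean posts.jsonl cleaned.jsonl
painlex filter1 cleaned.jsonl kept.jsonl --config config.yaml
painlex sarcasm kept.jsonl kept2.jsonl --config config.yaml --scores-out scores.csv
painlex embed kept2.jsonl vectors.txt --config config.yaml
painlex associate vectors.txt candidates.csv --config config.yaml
painlex score posts.jsonl emotions.csv
painlex count posts.jsonl stats.csv
painlex revise --out-questionnaire revised.json --out-report report.json
painlex run-all --config config.yaml --outdir out/
```

Exit codes: `0` success, `2` configuration error, `3` a stage emptied the
pipeline. `run-all` simulates a corpus and executes both rounds, writing
stage manifests (n_in / n_out / n_removed with conservation asserted),
candidate tables, descriptor statistics, the revised questionnaire, and
the revision report. Reruns with the same config and seed are
byte-identical.

Example YAML config:

```yaml
seed: 3
simulate:
  n_posts: 2000
  p_contains_pain: 0.7
  p_sarcastic: 0.05
  noise_vocab_size: 200
  post_length_range: [5, 9]
  lexicon:
    roots: [stabbing, burning, aching]
    associates:
      stabbing: [[puncturing, 0.9]]
    conditions: [migraine, arthritis]
    emotion_words:
      fear: [[terrified, 0.8]]
    sarcasm_markers: [totally]
keywords:
  mpq: null          # null -> the bundled 78 descriptors
  thesaurus: null    # null -> the default thesaurus stand-in list
filter:
  hop_limit: 3
  conditions: [migraine, arthritis]
sarcasm:
  threshold: 0.7
  markers: [totally]
embedding:
  dimension: 32
  context_window: 3
  min_count: 5
  epochs: 2
revision:
  decile: 0.1
  use_fixture_rules: false
emotion_lexicon: null   # path to a token/channel/intensity TSV; null -> demo
intensity_mode: neg_max
```

## Layout

- `src/painlex/synthetic_corpus.py` — seeded corpus generator + analytic
  count oracle
- `src/painlex/corpus_io.py` — post records, cleaning, both relevance
  filters, manual exclusions, JSONL/CSV I/O
- `src/painlex/word_graph.py` — token adjacency graphs, BFS hop distance
- `src/painlex/sarcasm_filter.py` — pluggable [0,1] sarcasm scorer, strict
  threshold filter
- `src/painlex/embedding_association.py` — skip-gram trainer, neighbor
  extraction, pruning, provenance
- `src/painlex/emotion_intensity.py` — lexicon-based channel scores,
  pain-intensity mapping, descriptor statistics
- `src/painlex/questionnaire_revision.py` — threshold derivation, removal /
  addition rules, psychological subclass, reordering, assembly
- `src/painlex/pipeline.py`, `src/painlex/cli.py` — orchestration, stage
  manifests, CLI
- `src/painlex/data/` — bundled questionnaire, comparison-table fixture,
  demo emotion lexicon
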