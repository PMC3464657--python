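# biomek

Meta-knowledge assignment for biomedical events. Given documents with
standoff event annotations (BioNLP-ST-style `.txt`/`.a1`/`.a2`) and
token-aligned dependency parses (`.conll`), the package:

- induces cue-word lexicons by pointwise mutual information (PMI threshold
  −1.5 in log base 2, configurable);
- extracts token, neighbouring-word, word n-gram, pair n-gram and
  shortest-dependency-path features, plus meta-knowledge-specific features
  (cue paths, sentence position, citation presence, stacked auxiliary
  scores), hashed into a 2^20-dimensional space with type-based L2
  normalisation;
- trains one-vs-rest L2-regularised squared-hinge linear classifiers with
  class-biased cost factors (negative:positive ratio per class);
- assigns one value per event for each of five dimensions — Knowledge Type
  (Investigation/Observation/Analysis/Fact/Method/Other), Certainty Level
  (L1/L2/L3), Polarity (Positive/Negative), Manner (High/Low/Neutral),
  Source (Current/Other) — and derives the New Knowledge and Hypothesis
  hyper-dimension flags;
- detects cues either by dictionary matching or with a learned token
  classifier (explicit NONE class, optional dictionary filter);
- transfers annotations between id-mapped corpora with an exact-match rule
  on event type, mapped id and core argument spans;
- evaluates per-value P/R/F with macro/micro averages and a majority-value
  baseline;
- generates synthetic standoff corpora (templates with known dependency
  structure, configurable value distributions, cue inventories, label
  noise, citations and positional Knowledge-Type bias) so the whole system
  is testable without any corpus download.

## CLI

```sh
biomek synth --seed 7 --out corpus/                 # synthetic gold corpus
biomek build-lexicon --train corpus/ --tau -1.5 --out lex.tsv
biomek train --train corpus/ --lexicon lex.tsv --out model.bin
biomek predict --model model.bin --in corpus/ --out pred/
biomek evaluate --gold corpus/ --pred pred/
biomek baseline --gold corpus/
biomek transfer --source src/ --target tgt/ --idmap idmap.json --out out/
```

`biomek train` supports the leave-one-feature-out ablation grid via
repeated `--disable-feature {cue-path,trigger,pair,sentence,citation}` and
the learning-setting switches `--no-bias-factors` / `--no-type-norm`.

## Annotation dialect

Tab-separated, UTF-8, 0-based half-open character offsets:

- `.a1` — entity text-bounds `T1<TAB>Protein 0 3<TAB>p53`;
- `.a2` — triggers and cue text-bounds (cue kinds `<Dim>-cue`,
  discontinuous spans as `start end;start end`), events
  `E1<TAB>Type:T2 Theme:T1 Cause:E2` (trigger-less events omit `:T2`),
  attributes `A1<TAB>KT E1 Observation` (five per event), cue links
  `#1<TAB>CueLink E1 KT T5`;
- `.conll` — per-sentence blocks with `# sent_id`, `# span`, `# parser`
  comments and `INDEX FORM LEMMA POS HEAD DEPREL` rows; several parsers per
  sentence are allowed and their features are kept in parser-distinct
  groups.
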