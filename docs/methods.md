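# Methods

## The model

`bionerkit` tags biomedical entity mentions (diseases, chemicals/drugs,
genes/proteins, species) in pre-tokenized sentences using the BIO scheme:
given a sentence X = {x₁, …, xₙ} the model predicts labels Y = {y₁, …, yₙ}
with yᵢ ∈ {O} ∪ {B-t, I-t : t an entity type}, and an entity is a maximal
B-then-I run of one type.

The architecture is a multi-feature embedding layer feeding a bidirectional
LSTM encoder and a linear-chain CRF:

1. **Embedding layer.** Each word is represented by the concatenation of up
   to four vectors, in fixed order:
   - *POS feature* (default 50 dims): the word's part-of-speech symbol,
     one-hot over the observed inventory plus an unknown bucket, projected
     by a jointly-trained linear map. The POS tagger is an injected
     dependency; the shipped default is a deterministic closed-class +
     suffix rule tagger with a Penn-Treebank-style inventory.
   - *Character feature* (default 50): a per-word character BiLSTM; the
     final forward and backward hidden states are concatenated. This is the
     component that generalizes to out-of-vocabulary surface forms.
   - *Character-LM ("data-specific") feature* (default 64 per direction):
     forward and backward character-level language models trained on the
     task corpus text with a next-character objective. The forward vector
     of a word is the LM hidden state after the word's last character in
     the running sentence stream; the backward vector is the reverse LM
     state after the word's first character. Trained LMs are frozen
     extractors, following the contextual-string-embedding convention.
   - *Contextual feature* (default 768): per-word vectors from a
     transformer-style subword encoder behind a pluggable contract
     (subword tokenizer, [CLS]/[SEP] boundary markers, padding to a fixed
     `max_length` of 128 subwords, per-subword hidden vectors). Words are
     aligned to their **first** subword by default (mean-pooling is a
     config alternative); boundary and padding vectors are discarded.
2. **Encoder.** A BiLSTM with 256 units per direction (output width 512)
   over the concatenated vectors; a fully connected layer maps the 512-dim
   outputs to k emission scores, one per label.
3. **CRF.** The chain score is
   Score(X, Y) = Σᵢ₌₁ⁿ P[i, yᵢ] + Σᵢ₌₀ⁿ T[yᵢ, yᵢ₊₁]
   with y₀ = start and yₙ₊₁ = stop: two augmented states carry learned
   boundary transition scores, so T is (k+2)×(k+2). Training minimizes the
   negative log-likelihood log Z − Score(X, Y_gold), with log Z computed by
   the forward recursion in log-space; gradients are the forward–backward
   marginals minus gold indicators. Decoding is Viterbi:
   Y* = argmax_Y Score(X, Y).

## Constraints

The transition matrix is *learned*, but a hard boolean mask (default on)
additionally clamps structurally invalid BIO transitions — a sentence may
not start with I-t, and I-t may only follow B-t or I-t of the same type —
to a large negative sentinel (−10⁴) at both loss and decode time. The
sentinel rather than −∞ keeps every quantity finite and differentiable;
it is far below any reachable path score, so masked transitions never
appear in decoded output (verified over 10⁴ random decodes). Whether a
valid path exists at all is decided exactly by boolean reachability over
the mask, not by score thresholds. Gold training data violating the mask
is rejected with the offending sentence indices.

Viterbi ties are broken deterministically by taking the lowest label index
at every backpointer and at the final state.

## Training protocol

The provided training and development files are merged into one pool and a
seeded 10% split of the pool is held out for validation; the test file is
untouched. Optimization is AdamW (the original work does not name its
optimizer) with gradient-norm clipping at 5.0; dropout (default 0.5) is
applied to the encoder output. Early stopping monitors validation strict
entity-level F1 with patience 10 (also unstated in the original; chosen to
make the 100-epoch cap practical); the best-validation checkpoint is
returned. Batches are length-bucketed and processed sentence-by-sentence —
batching is a gradient-accumulation unit, not a vectorization unit, which
makes padding invariance exact by construction on CPU and keeps runs
bit-reproducible from the seed.

Per-dataset presets ship the published hyperparameter selections
(max_length 128; batch 64, or 32 for LINNAEUS and BC4CHEMD; hidden 256;
learning rates 5e-5 / 5e-3 / 1e-3 / 3e-5 per dataset; 100 epochs max).
Sentences whose subword expansion exceeds the budget are skipped with a
warning at training time and truncated at prediction time (words with no
surviving subword receive zero contextual vectors), keeping prediction
total.

### Trained vs frozen components

The POS projection, character encoder, BiLSTM, emission projection and CRF
transitions are trained jointly. The character LMs and the contextual
backend are frozen feature extractors: char-LM embeddings are conventionally
used frozen, and the shipped contextual backend is a fixed mock (below), so
fine-tuning it would be meaningless. The contract leaves room for a real
transformer backend; freezing is then still the default behavior of this
implementation.

The POS projection is trained jointly with the tagger (the alternative — a
fixed random projection — is not exposed). The char-LMs are trained on
training text only, never on test text, to avoid leakage.

## Evaluation

Strict entity-level matching: a predicted span counts as a true positive
only when (start, end, type) all equal a gold span's; partial overlaps
count as both a false positive and a false negative. P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2PR/(P+R); when a denominator is zero the metric is
reported as 0 (the common chunk-evaluation convention; configurable).
Pooled metrics are micro-averages (summed counts). Predicted tag sequences
are converted to spans leniently (an orphan I-t starts a span); gold data
strictly.

## Synthetic fixtures

The generator plants dictionary entities into templated filler sentences:
two default types (Disease, Gene) with productive morphology — lowercase
stems + suffixes ("nephritis", "chronic arthrosis", "derm oma syndrome")
versus uppercase alphanumeric identifiers ("IL-2", "TP-53", "EGFR-10R
receptor") — plus short abbreviations, with type-specific cue words emitted
next to entities 80% of the time. Entity counts per sentence are Poisson
(mean 1.2, truncated to fit); sentence frames are 6–14 filler tokens. The
train/test split holds out 20% of each type's surfaces so the test set
probes out-of-vocabulary generalization.

What this does **not** emulate: real tokenization noise, nested or
discontinuous mentions, annotation inconsistency, long sentences, document
structure, or realistic type confusability. A high fixture F1 shows the
pipeline learns and scores correctly — it is not a claim about benchmark
performance.

The mock contextual backend chunks words into ≤4-character subwords, maps
each through a seeded hash-indexed random embedding table, and applies one
fixed mixing layer that adds a mean over the sentence's real subwords —
deterministic, contextual, and provably padding-invariant (padding
positions are excluded from the mean and output zeros). It satisfies
exactly the contract a real transformer backend must satisfy.

## Desk-scale recipe

The reference run (`bionerkit.recipes.fixture_learnability_run`) trains the
full model on a 500-sentence fixture with the mock backend at reduced
dimensions — encoder 32/direction, POS 16, char 16, char-LM 24, contextual
32, batch 16, learning rate 2e-3, dropout 0.2, ≤30 epochs, patience 5 —
because the synthetic task saturates quickly and the full-size model only
adds runtime. On one CPU the run takes about two minutes and reaches
held-out strict F1 ≈ 0.99 including OOV surfaces.

## Numerical choices

- All arithmetic is float64; partition computations use log-space with
  max-shifting and are stable for per-term scores up to ±10³.
- LSTM forget-gate biases are initialized to 1; other weights are uniform
  in ±1/√fan.
- The CRF gradient is analytic (forward–backward marginals); it agrees
  with central differences to better than 10⁻⁴ relative error, and Viterbi
  and the partition agree with exhaustive enumeration to 10⁻⁸ on small
  instances (both checked in the test suite and the acceptance script).
- Degenerate inputs: empty corpora, empty words, zero-entity specs,
  overlapping spans and invalid gold sequences all raise explicit errors;
  a fully masked transition structure raises a decode error rather than
  returning the sentinel.

## Known limitations

- The recurrent layers are plain numpy and process sentences sequentially;
  throughput is desk-scale, not GPU-scale. Benchmark-size training is out
  of scope here.
- One encoder layer only; stacked encoders are not implemented.
- No real transformer checkpoint loader is bundled; the contextual
  contract accepts one, but only the mock backend ships.
- The rule POS tagger is intentionally simple; for serious use inject a
  real tagger through the `PosTagger` contract.
- BIOES/IO tag schemes, nested entities and document-level normalization
  are out of scope.
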