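# Methods

## Problem setting

A screening corpus is m bibliographic records (id, title, abstract) of
which P are *relevant* — actually included by the target systematic
review — and m − P were retrieved by the search but excluded. Realistic
shapes are m between roughly 10² and 10⁴ with P between 5 and 20. The
package simulates prioritized screening retrospectively: the labels act as
the oracle a human reviewer would provide one article at a time.

## Text processing

Titles and abstracts are concatenated with a single space; titles carry
the strongest topical signal and title/abstract records are what screeners
see. Tokenization lowercases and splits on any non-alphanumeric character,
keeping stopwords and numerals. For English this is where morphological
segmentation degenerates to, since orthography already separates words.
The vocabulary is the `max_vocab` (default 1000) most frequent words,
descending frequency with lexicographic tie-break, making it invariant to
article order. Out-of-vocabulary tokens are dropped before training.

## Embedding model

Word vectors W (n × k) and document vectors D (m × k) are trained jointly
by a single negative-sampling objective with a shared output layer C:
skip-gram pairs (center word → context word within a dynamically shrunk
window) update word rows, PV-DBOW pairs (document → each of its words)
update document rows. Parameters, defaults, and rationale:

| parameter    | default | why |
|--------------|---------|-----|
| k            | 300     | standard dimension, sufficient for word/document features |
| negative     | 5       | appropriate for corpora of 10²–10⁴ documents |
| max_vocab    | 1000    | most-common-words restriction keeps training tractable |
| epochs       | 40      | small corpora need many passes; declared default of this implementation |
| window       | 5       | common skip-gram default; declared, not inherited |
| subsample    | 1e-3    | word2vec frequent-word downsampling threshold |
| alpha→min_alpha | 0.025→1e-4 | linear decay over all epochs, word2vec recipe |

Initialization is uniform(−0.5/k, 0.5/k) for input rows, zeros for the
output layer; noise words are drawn from the unigram^0.75 distribution.
An article with no in-vocabulary tokens still gets a D row: the zero
vector, whose cosine to anything is undefined and therefore ranks last.
A `joint=False` flag trains W first and then fits D against the frozen
output layer; the simultaneous mode is the default.

### Numerical choices

The trainer is vectorized minibatch SGD (default batch 2048). Within a
batch, gradients hitting the same embedding row are *averaged*, not
summed: under a Zipf vocabulary the most frequent word can appear hundreds
of times per batch, and summed scatter-updates give it an effective step
of lr × count, which empirically blows the matrices up into a rank-1
collapse (every cosine ≈ 1). Averaging bounds every row's step by the
learning rate; for rows appearing once it is plain SGD. Training runs in
float32 (the updates are memory-bandwidth-bound) and the final matrices
are returned as float64. All randomness flows from one seeded generator,
so deterministic mode is bit-reproducible on the same machine; there is no
multi-threaded Hogwild path.

The feature matrix is F = D Wᵀ, kept at full width n (no SVD or other
low-rank approximation). Cosine of a zero-norm vector is the sentinel
`None` ("undefined"), never a number.

## Screening loop

Seeds are two distinct relevant articles and count as reads 1 and 2. Each
subsequent step scores all unscreened articles by cosine to
q = mean(screened-relevant rows) − mean(screened-irrelevant rows), the
subtracted term omitted until an irrelevant article has been read. The
canonical update is this mean-minus-mean form throughout; it is recomputed
after every single read. Ranking is by similarity descending; undefined
scores rank below all defined ones; exact ties (and the all-undefined
degenerate case, e.g. a zero query) break to the lexicographically
smallest id, making the whole trace deterministic given F and the seed
pair. Only unscreened articles are rescored — screened ones need no rank.
The loop stops when all P relevant articles are screened, or after an
optional total-read budget (an extension for prospective use, off by
default).

The production loop is vectorized over sorted-id position arrays; its
gather order and arithmetic expressions mirror the op-level functions
(`update_query`, `score_unscreened`, `select_next`) exactly, and the test
suite holds it to identical traces against a from-scratch per-article
reference loop.

## Evaluation

* **WSS@R** = (N − n_read)/N − (1 − R/100) with n_read the first read
  count at which ⌈R/100 · P⌉ relevant articles have been screened; no
  interpolation between steps. It is computed as the algebraically equal
  R/100 − n_read/N so that WSS@100 equals 1 − reading-ratio bit-exactly.
  A trace that never attains R% recall (possible under a budget) yields a
  result flagged unattained rather than a number.
* **AUROC** at a step is the Mann–Whitney probability that a random
  relevant article outscores a random irrelevant one (ties ½), computed
  over the *unscreened* pool with the scores used for that step's
  selection (computed via `sklearn.roc_auc_score`; an exhaustive
  pair-counting oracle cross-checks it in the tests). Steps with a
  single-class pool or no defined scores are undefined and omitted from
  aggregates — imputing 0.5 would manufacture discrimination where none is
  measurable. A run's "final AUROC" is the last defined step's value.
* **Seed-pair sweep**: one run per C(P,2) pair; WSS@95, WSS@100 and final
  AUROC aggregated as mean, sample SD (0 when only one pair), min, max.
  AUROC dispersion across steps is reported as across-run mean ± SD; no
  analytic confidence interval is implemented.

## Synthetic corpora

The generator emulates the *structure* of labeled screening datasets, not
their semantics: a background vocabulary with Zipf(1.0) rank-frequency
(so the most-common-words cap is actually exercised) and a disjoint topic
vocabulary. Each token of a relevant article comes from the topic
distribution with probability `delta`, else from the background;
irrelevant articles draw from the background only. Token counts are
positive-truncated normal (default mean 120, SD 30, roughly abstract
length plus title); the first 8 tokens form the title. Defaults
vocab_size = 1200 (a realistic distinct-word count for corpora of this
size, stopwords included) and topic_size = 100. `delta=0` makes labels
independent of text; `delta=1` makes relevant articles purely topical.
Eight preset configurations mirror the (P, m) shapes of real reproduced
review datasets, from (5, 138) to (20, 6935).

What passing tests on this generator do **not** show: robustness to
near-boundary exclusions (excluded articles about the same topic), to
heterogeneous sub-topics among relevant articles, or to real English
syntax and named entities. A unigram mixture with disjoint topical words
is an easy case by construction; the separable benchmark is a
plumbing-and-learning check, not a claim about real-world WSS.

## Benchmark problem sizes

The self-contained benchmarks use the smallest realistic shapes: the
separable benchmark trains the full published configuration (k = 300,
1000-word vocabulary, 40 epochs) on the (P=5, m=138) preset and sweeps all
10 seed pairs; the null-control benchmark runs 50 replicate corpora
(m=200, P=10, delta=0) with a reduced configuration (k = 64, 10 epochs,
500-word vocabulary) — the null property (labels independent of text ⇒
mean WSS@95 ≈ 0) does not depend on embedding capacity, so the smaller
model is used there to keep the replicate count high. Note the null
expectation is not exactly 0: with small P, the ⌈·⌉ recall threshold and
the two pre-read seeds bias random-order WSS@95 slightly positive
(order-statistics effect, ≈ +0.04 at these sizes), well within the ±0.10
band checked.

## Known limitations

* No stopping criterion for prospective use beyond a fixed budget; the
  retrospective stop rule needs the full label oracle.
* Embeddings are retrained per corpus; there is no transfer from larger
  collections and no contextual/transformer encoder.
* The trainer is a single-threaded CPU implementation; corpora around
  m ≈ 10⁴ train in minutes, not seconds.
* Deduplication across databases and full-text screening are out of scope.
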