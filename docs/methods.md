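# Methods

This note documents the models, defaults, numerical choices and known
limitations of `protlm`, in the order data flows through the package.

## Datasets (`io_seq`)

Three evaluation sets are supported: *generated* (model emissions that ended
with an end-of-sequence token within the generation budget), *natural*
(user-supplied FASTA), and a *random* control built by concatenating symbols
drawn uniformly from the 25-letter residue alphabet seen in large sequence
databases — the 20 standard amino acids plus the IUPAC codes B, O, U, X, Z,
fixed in alphabetical order for determinism (every uppercase letter except
J).

Sequence lengths for synthetic sets are drawn from a normal distribution
truncated by resampling to `[min_len, max_len]` (defaults 5–267 residues).
The distribution's moments default to the midpoint of the window and one
sixth of its range (mean 136, sd ≈ 43.7), i.e. a spread that covers the
window without piling mass at the bounds; both moments are configurable, so
a length model matched to a specific natural set is a one-line change.

Validation splits hold out `floor(fraction · N)` sequences (clamped to keep
both halves non-empty), selected by a seeded permutation; the same seed
always reproduces the same partition. Length matching is seeded rejection
sampling over random n-subsets with a budget of 10,000 draws; on failure the
error reports the closest moments achieved so the caller can see how far the
pool is from the target. Rejection is preferred over greedy selection
because it leaves the subsample exchangeable (no length-ordering bias).

FASTA reading is strict — a body line before any header or a header with an
empty body raises an error naming the line — because silent skips in corpus
assembly corrupt every statistic downstream. Writing is 60-column wrapped.

## Tokenizer

Byte-pair encoding over residue strings. Each sequence is one BPE "word":
merges never cross sequence boundaries, and no whitespace or byte-level
mapping is involved. Specials are `<eos>` (id 0) and `<unk>` (id 1); base
characters follow in alphabetical order, then merged tokens in training
order, so ids are dense from 0 and reconstructible from the merges file
alone. Training repeatedly merges the most frequent adjacent pair, stopping
when the vocabulary budget is reached or no pair occurs at least twice; ties
break on the lexicographically smallest pair, making training fully
deterministic. Encoding replays merges lowest-rank-first, which is
equivalent to applying them in training order. Characters outside the
training alphabet encode to `<unk>` and are tallied in `unk_counts` rather
than raising, so natural data with rare codes passes through visibly.

The full-scale vocabulary size used for large protein corpora (50,256
tokens, averaging about four residues per token) is kept as the
`PAPER_SCALE_VOCAB` preset; desk-scale vocabularies of a few dozen tokens
exercise exactly the same code paths.

## Language model (`lm`)

A pre-norm decoder-only transformer: learned token and positional
embeddings, per-block layer norm → causal multi-head scaled dot-product
attention → residual, layer norm → 4× GELU MLP → residual, final layer norm
and an **untied, zero-initialized output head**. Zero-initializing the head
makes a freshly constructed model emit the exact uniform distribution 1/V,
giving analytic anchors (loss ln V, perplexity V) that the test battery
checks to 1e-6. Other weights are N(0, 0.02), with residual projections
scaled by 1/√(2·layers). Parameters are float64; forward, backpropagation
and Adam are hand-written in numpy and verified against central finite
differences (relative tolerance 1e-4) in the test suite.

Desk defaults: 4 layers, width 128, 4 heads, context 256. The acceptance
computations use an even smaller 2-layer/width-32/context-64 model, which is
ample for the synthetic grammars and trains in seconds per hundred steps on
one CPU core. The full-scale shape (36 layers, width 1280, 20 heads,
512-token blocks, 65,536 tokens per batch) exists as `paper_scale_config()`
for reference and is never exercised in tests.

Training: sequences are tokenized, joined with one `<eos>` after each, and
chunked into context-length blocks (a trailing block with fewer than two
tokens is dropped — nothing to predict). Batches are drawn without
replacement within an epoch from a seeded permutation. The optimizer is
Adam (β₁ = 0.9, β₂ = 0.999, lr 1e-3 by default) with global-norm gradient
clipping at 1.0, added for desk-scale stability; the learning rate is
constant. Loss is the mean negative log-likelihood per predicted position in
nats, computed with a max-subtracted log-softmax; padded positions carry
target −1 and are masked out. Validation loss is computed only on blocks
built from the held-out split. Reproducibility is claimed per hardware
class: same seed, same platform → bit-identical traces.

## Decoding (`decode`)

The transform pipeline is fixed and documented: **repetition penalty (on
logits) → temperature → softmax → top-k → top-p → renormalize → select**.
The repetition penalty divides positive logits of context tokens by the
penalty and multiplies non-positive ones by it (the standard conditional-
generation rule); top-k ties at the k-th probability break toward the lower
token id (stable sort); the nucleus filter keeps the smallest
probability-sorted prefix with cumulative mass ≥ p and always keeps at least
one token, so no filter chain can produce a degenerate all-zero vector.

Beam search scores candidates by the sum of log-probabilities after the
penalty/temperature transforms (no length normalization; a documented
consequence is that `beam_width=1` reproduces greedy decoding for every
configuration, and with the identity transforms the score is exactly the raw
model log-probability, making an exhaustive beam equal brute-force
enumeration). EOS-completed beams are retired and compete by total score.
`GenerationResult.logprob` is always the raw (untransformed) model
log-probability of the emitted non-EOS tokens. The generation budget
defaults to 250 new tokens; a sequence still running at the budget is
flagged `terminated=False` and excluded when evaluation sets are assembled.
Prompts are optional — generation can start from an empty context (the model
sees a single EOS as the left boundary) or from a residue prompt.

## Calibration (`calibrate`)

For each grid cell (repetition penalty, top-k, top-p), `samples_per_cell`
sequences are sampled with seeds spawned deterministically from the master
seed, truncated generations are filtered out, and the survivors' pooled
residue frequencies are compared to a natural reference profile. The
distance is L1 over the reference's `n_focus` (default 7) most common
residues — chosen because the propensity mismatch of a bad sampling
configuration concentrates in the high-frequency residues — with
full-alphabet L1 reported as a secondary column. Cells whose generations
were all truncated are flagged with NaN distances rather than dropped.
Ranking is ascending by focus distance with (penalty, k, p) lexicographic
tie-break, so the output table is a total order reproducible bit-for-bit
under a fixed seed. Beam-search cells are excluded from the default grid;
deterministic strategies can be swept separately if desired. The historical
full sweep (1.1–3.0 × 0.1, 250–1000 × 50, 0.70–1.00 × 0.05 → 2240 cells) is
`paper_grid()`.

## Homology statistics (`evalstats`)

The HSSP curve is implemented as t(L) = max(A·L^B, plateau) with A = 290.15,
B = −0.562, plateau = 24.8 %. The `max` form places the plateau breakpoint
at the true crossover (L ≈ 79.6) rather than a hard-coded length, which
keeps the threshold monotone non-increasing and exactly continuous — both
properties the classification logic relies on. The parameterization is a
plain dataclass, so alternative twilight-zone curves can be swapped in.

Classification uses strict inequality (identity must exceed the threshold).
Best-hit selection filters to above-curve hits and picks the longest
alignment, breaking ties by identity (length-primary, per the convention
that a long marginal alignment is stronger evidence of relatedness than a
short high-identity one); if nothing clears the curve the hit closest to it
(max identity − threshold) is reported as below-curve. Dataset summaries
count queries without any hit as below the curve.

Hit tables use a normalized TSV dialect (query, target, prob, identity,
aln_length, qstart, qend) rather than any upstream tool's native report, so
the parser is not coupled to a specific search-tool version; parse errors
name their line number and nothing is silently skipped. Disorder files are
whitespace-separated (position, residue, score in [0, 1]); ordered content
is the percentage of residues with score strictly below the cutoff (default
0.5, the IUPred convention — configurable). Secondary-structure files carry
(position, residue, state H/E/C, three per-state probabilities); the integer
confidence 0–9 is floor(10·max probability) capped at 9, and content
percentages are computed only over residues with confidence ≥ 5 (default),
returning not-available rather than zeros when no residue qualifies.

## Similarity networks (`network`)

Edges require an alignment of at least 20 residues with at least 70 %
search probability (both configurable). A query whose qualifying alignments
fall in non-overlapping query regions is split into one suffixed node per
region (`id#1`, `id#2`, …, generalized to any number of regions); two
intervals count as overlapping when they share more than 10 % of the
shorter interval (single-linkage grouping, tolerance configurable). Both
directions of an asymmetric all-vs-all table collapse to one undirected
edge; self-hits are ignored. The graph container and connected components
are networkx; component lists are sorted largest-first with a lexicographic
representative tie-break, and the test suite checks them against an
independent hand-written BFS closure.

## Synthetic grammars (`synthetic`)

First-order Markov chains with configurable alphabet, initial distribution,
transition matrix and truncated-normal length distribution. The entropy
rate H = Σᵢ πᵢ Σⱼ −Pᵢⱼ ln Pᵢⱼ (stationary π from the unit left eigenvector,
polished by power iteration to 1e-10; irreducibility checked by strong
connectivity) is the optimal cross-entropy any model can achieve, giving
training an absolute target. The repository's standard grammars are the
symmetric two-state stay-0.9 chain (entropy rate ≈ 0.3251 nats/symbol) and
a fixed three-symbol asymmetric chain (seed 7).

`recovery_report` measures cross-entropy and per-state conditional total
variation **over transition positions only** — positions whose target and
predecessor are both alphabet symbols — with the model distribution
renormalized over the alphabet. This deliberately excludes end-of-sequence
bookkeeping: the grammar's entropy rate carries no length model, so charging
the model for EOS prediction would add a spurious ≈ 0.04-nat gap that says
nothing about transition recovery. An untrained (uniform) model therefore
shows a gap of exactly ln V_alphabet − H.

What the generator does *not* emulate: real protein corpora have
long-range dependencies, domain structure, compositional heterogeneity and
phylogenetic redundancy that first-order chains lack. Passing the recovery
battery shows the training loop, loss accounting and decoding machinery are
correct — it does not show that a desk-scale model trained on these corpora
generalizes the way a full-scale model trained on tens of millions of
natural sequences does.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 300 grammar sequences
(lengths 30–200, mean 120), 2-layer/width-32 models trained for 250–400
Adam steps, 100 random beam-enumeration fixtures (vocab ≤ 4, length ≤ 4),
1000 random filter vectors, 10,000 random sequences for the BPE round-trip,
and ten 50-node random graphs. These sizes are chosen so every check has a
sharp expected value (analytic or oracle-computed) while the whole battery
runs in about a minute on one CPU core.

## Known limitations

* Training is single-device, constant-learning-rate, full-precision numpy;
  there is no warmup/decay schedule, dropout, or mixed precision. The
  full-scale preset is a shape, not a trainable configuration here.
* The repetition penalty applies to the set of all context tokens without a
  recency window.
* The calibration reference profile is whatever FASTA the caller supplies;
  no database sampling is built in.
* The HSSP parameterization has published variants; the default here is the
  classic two-parameter form, and results near the curve shift with the
  variant chosen, which is why the curve is pluggable rather than a
  constant.
* Upstream predictors (profile-HMM search, disorder and secondary-structure
  prediction, structure prediction and refinement) are out of scope; only
  their tabulated outputs are consumed.
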