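# Methods

`rxnbench` implements a complete predictive-scenario harness for chemical
reaction prediction — task construction, augmentation, format/tokenization
variants, embedding strategies, a seq2seq translator, and an evaluation
suite built around retrosynthesis-aware metrics — exercised end to end on
synthetic template reactions. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic data
does and does not establish.

## Synthetic reactions

Real patent-derived reaction corpora have a characteristic shape: one to
five reactant molecules per reaction (median 2, mean ≈ 1.78, std ≈ 0.47)
and zero to twenty-one reagents (median 3, mean ≈ 3.03, std ≈ 2.22), with
every product reachable from its reactants. The generator reproduces that
shape without a reaction-rule engine:

* A **template** is a string-grafting rule. Reactants are drawn from the
  template's own fragment pool (three chain-safe fragments per template;
  one or two fragments are concatenated per reactant), and the product is
  the canonical molecule obtained by joining the *sorted canonical*
  reactant strings with the template's linker group (e.g. `C(=O)N`,
  `OC(=O)`, or direct coupling). Fragments start and end at atoms with
  spare valence and close all rings internally, so every graft parses;
  this is validated exhaustively in the test suite.
* Because the transform sorts canonical reactant strings first, the
  product is a pure function of the reactant *multiset*: reactant order
  and surface spelling never change the product. Every record therefore
  has a forward oracle (its own template), and a perfect forward predictor
  exists by construction.
* Reactant species within one reaction are distinct (as in curated
  reaction corpora), and the oracle forward model consumes the
  *deduplicated* canonical reactant set. Together these make the molecule
  set determine the multiset, so every strict top-1 hit is guaranteed to
  round-trip.
* **Reactant counts** follow a fixed categorical law on 1–5 with
  probabilities (0.245, 0.728, 0.022, 0.004, 0.001): median 2,
  mean 1.788, std ≈ 0.50.
* **Reagent counts** follow a negative binomial with r ≈ 4.836 and
  p ≈ 0.615 (method-of-moments fit to mean 3.03, std 2.22), truncated to
  0–21 by rejection. Simulation at n = 10,000 gives sample mean within
  ±0.15 of 3.03 and sample median exactly 3 across seeds; the test suite
  asserts this.
* Reagents are drawn without replacement from the template's 24-molecule
  reagent pool (solvents, bases, additives). Two pool members (a
  sulfoxide and a sulfonic acid) fall outside the SELFIES codec subset on
  purpose, so the `?` fallback appears naturally in converted datasets.
* Records are single-product by default; a config switch adds a water
  byproduct to a fraction of records for multi-product testing.

Splits use largest-remainder rounding, so any fraction triple partitions
any n exactly.

**What the generator does not emulate:** real chemistry (no mechanism, no
selectivity, no atom mapping), the scale of patent corpora (480k
reactions), chirality and charged species, and the long tail of rare
reaction classes. Tests passing on this data validate the *pipeline
contracts* — determinism, chemistry preservation, metric semantics,
learnability — not chemical accuracy on real reactions.

## Molecule-string services

Canonicalization is RDKit's canonical SMILES (toolkit and version are the
reproducibility anchor; they are recorded in run metadata). Randomized
SMILES are produced by uniformly permuting the atom order before
serialization, which randomizes the root atom and the branch/ring
enumeration direction. Multi-molecule strings are stored as lists and
joined with `.` only at serialization, so the separator is unambiguous.

### SELFIES codec

No SELFIES implementation is part of the runtime environment, so the
package ships its own codec for the neutral organic subset
{C, N, O, S, P, F, Cl, Br, I} with single/double/triple bonds, branches
and rings (aromatic systems are kekulized before encoding). It implements
the defining derivation semantics: bond orders are clamped to remaining
valence, branch lengths and ring offsets are read from index tokens, and
impossible instructions are skipped — so *every* well-formed token string
decodes to a valid molecule, which the test suite checks on random token
soup. Molecules outside the subset (charges, isotopes, stereocenters,
hypervalent S/P, multi-fragment strings) are not encodable and map to the
single fallback token `?`, which is carried through datasets verbatim and
is not decodable. Round-trip canonical equivalence is asserted for every
encodable molecule in the synthetic library.

## Augmentation

Augmentation is source-only: each sample contributes the untouched
original plus (factor − 1) variants whose source molecules are re-rooted
randomized SMILES in randomly permuted order; targets are byte-identical.
The original is always the first copy, so factor 1 reproduces the input
exactly. Variants are sampled with replacement from the randomized-string
space — small molecules have few distinct enumerations and deduplication
is deliberately not attempted. A `permute_molecules=False` switch keeps
source order fixed (useful when the source mixes roles, as in reagent
prediction where reactants and product share the input). Permutation is
uniform over all source molecules regardless of role, since the joined
input carries no role marker.

## Tokenization

Atom-level tokenization follows the molecular-transformer regex: bracket
atoms, two-letter elements, ring-closure digits (incl. `%nn`), bonds and
parentheses are single tokens; SELFIES tokenizes per bracket group. Both
are lossless (token concatenation reproduces the input).

Pair encoding iteratively merges the most frequent adjacent token pair,
with three fixed choices: merges never cross the `.` separator (substrings
must be intramolecular), ties break lexicographically (the reference
algorithm is silent), and the stopping rule applies to **merge-formation
frequency** — merging stops when no pair reaches the threshold. The
alternative reading (thresholding the *final* substring frequency after
later merges absorb earlier ones) would prune intermediates; we keep them
in the vocabulary with their post-merge counts. The reference threshold of
2000 occurrences is a property of corpus scale; at desk scale it is a
config knob (default 50 in the experiment pipeline) and no vocabulary-size
target is enforced.

## Embeddings

The pre-trained-embedding condition uses skip-gram with negative sampling
(5 negatives, window 5, embedding size 256 at reference scale, 64 at desk
scale) over a corpus of single molecules — each reactant, reagent and
product is one sequence, so co-occurrence is purely intramolecular and the
`.` separator never appears. Skip-gram was chosen over CBOW as the common
default for small corpora; the choice is recorded in table metadata.
Specials (`<pad>`, `<unk>`, `<bos>`, `<eos>`, `?`, `.`) get zero vectors
since they never occur in single-molecule text. The learning rate decays
linearly over the run as in reference word2vec — without decay, token
vectors on small corpora collapse onto a dominant direction. Updates are
minibatched for speed, with each token's per-batch movement capped at norm
0.5: the reference implementation updates pair by pair, where sigmoid
saturation self-limits drift, and batched accumulation needs the explicit
cap to stay stable on small vocabularies. Training is single-threaded
numpy and deterministic per seed. Epoch count and
negative-sampling rate are recorded in metadata, not asserted in tests.

## Translator

The translator is an in-repo encoder–decoder transformer on a minimal
numpy autograd engine: pre-norm residual blocks, sinusoidal positions,
scaled dot-product multi-head attention, ReLU feedforward, Adam with
linear warmup and inverse-sqrt decay, token-budget batching, and
beam-search n-best decoding. The reference preset matches the molecular
transformer (4 layers, d=256, ff=2048, 8 heads, 4096-token batches, beam
10, patience 10, validation every 10k × augmentation-factor steps); the
desk preset (2 layers, d=64, ff=256, 4 heads, 2048-token batches,
validation every 200 × factor steps) trains a toy task on one CPU in
minutes. Early stopping halts training when neither validation token
accuracy nor perplexity has improved for `patience` consecutive
validations; the best-accuracy parameters are restored afterwards.

Numerical choices: float32 throughout; gradient clipping at global norm 1;
dropout 0.1 on embeddings and sublayer outputs (configurable; the
copy-task oracle disables it, where regularization measurably hurts an
exactly learnable mapping); beam candidates are ranked by
length-normalized log-probability (mean per generated token) —
unnormalized sums measurably bias short hypotheses and token deletions on
exact-sequence tasks. Candidates that fail
detokenization downstream are kept as raw strings; scoring treats them as
invalid molecules. With frozen input embeddings, the source embedding
matrix is excluded from the optimizer and verified bit-identical after
training. Inference is deterministic for a fixed checkpoint (stable
argsort breaks score ties).

## Evaluation suite

* **Strict hit**: the canonical molecule *set* of the candidate equals the
  target's. Sets, not multisets — duplicated predictions neither help nor
  hurt. Any unparseable molecule makes the candidate a miss.
* **Lenient hit**: the canonical sets intersect; unparseable molecules are
  dropped individually.
* **Top-k**: fraction of records with ≥1 hit in the first k candidates.
  Beam output is scored at raw ranks, without canonical deduplication
  across ranks (a dedup switch is available but off by default, since the
  raw n-best list is what the decoder ranks).
* **Round-trip**: rank-1 predicted reactants (plus the true reagents when
  the models were trained with reagent information) go to the matched
  forward model; success means its rank-1 product strict-matches the true
  product. Matching compares products only, not reagents echoed in the
  source. With the template-oracle forward model, any precursor set the
  template maps to the true product counts — by construction a superset of
  strict top-1 hits, so round-trip accuracy ≥ strict top-1. Because the
  string-grafting transform canonicalizes and sorts its inputs, precursor
  decompositions on synthetic data are nearly unique and the two metrics
  typically coincide at desk scale; real reaction corpora, with genuinely
  distinct routes to one product, are where the gap grows.
* **P/R/F at rank k**: N = unique canonical molecules pooled over the
  top-k candidates (unparseable molecules excluded from N but counted in
  the invalid-candidate rate); T = |prediction ∩ target|; P = T/N with
  P = 0 when N = 0, R = T/M, F = 2PR/(P+R) with F = 0 when P + R = 0.
  M = 0 is an error: a reagent-task record with no target reagents should
  have been skipped at task construction.
* **Binning**: records are grouped by number of target reagent molecules;
  bins with more than 12 reagents or fewer than `min_bin_n` records
  (default 20; 10 in the desk pipeline) are discarded; the pooled value is
  the bin-size-weighted mean, which provably equals the direct mean over
  retained records.
* **Expert agreement**: labels are wrong / semi-correct / correct per
  group; "not wrong" = semi-correct or correct; "contradictory" = exactly
  one group says wrong. Counts partition the total; percentages are
  reported both exact and rounded to integer percent. Group identity is an
  opaque label — no expertise weighting, no kappa statistics.

## Desk-scale problem sizes

The experiment pipeline defaults to 5,000 generated reactions with an
85 / 6.25 / 8.75 split, the desk model preset, ≤2,500 training steps, and
beam 10 — sizes chosen so a full scenario cell (generate, train, decode,
score) completes in minutes on a single CPU. The copy-task sanity oracle
uses 2,000 molecule strings (library molecules plus randomized-SMILES
variants). The acceptance script trains three scenario cells (forward,
retro, reagent) at 3,000 reactions and 1,200–2,000 steps each.

## Known limitations

* The synthetic chemistry is structural, not mechanistic; absolute
  accuracies on it say nothing about accuracies on patent data.
* The SELFIES codec covers the neutral organic subset only; coverage on
  arbitrary external molecules would require extending the valence table
  and charge handling.
* The translator is CPU-oriented; reference-preset training at corpus
  scale is out of scope.
* Per-group expert rates depend on per-group contingency tables that the
  two-group summary (both/contradictory counts) does not determine.
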