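# Methods

This note documents the models, conventions and design choices behind the
toolkit, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model and standoff conventions

A corpus is a keyed set of snippets; each snippet pairs a plain text with
span annotations (T-lines) and trigger→entity relations (R-lines). All
offsets are **0-based, half-open, character-counted**; newlines are
normalized to `\n` before any offset arithmetic, and files are UTF-8, so a
snippet containing multi-byte characters round-trips with surface/offset
agreement. Discontinuous spans are parsed and preserved as fragment lists
(BRAT `;` syntax) with fragment surfaces joined by single spaces;
rejecting them would make the reader unusable on real BRAT corpora, so
their matching semantics are defined in the scorer instead. Unknown BRAT
line kinds (`#`, `A`, `E`, `M`, `N`, `*`) are skipped with a logged
notice rather than erroring. In relations, the `Arg1:` slot names the
trigger annotation and `Arg2:` the entity; validation enforces that the
trigger endpoint carries a trigger label and the argument endpoint an
entity label. A `.txt` without a matching `.ann` is read as an
unannotated snippet, which is what bare-text prediction inputs look like.

The label schema (ten entity labels in four categories, two trigger
labels, two roles) is frozen as the default but loadable from YAML,
including the fine→category map used for high-level scoring; the default
category names are COMPOUND, REACTION_CONDITION, YIELD, EXAMPLE_LABEL.

## Matching and scoring

Exact span matching requires identical fragment lists; relaxed matching
requires at least one character of overlap between any fragment pair
(half-open adjacency is not overlap). Relaxed matching relaxes spans
only — label agreement (fine or high-level) is always required. High-level
matching collapses entity labels to their category; trigger labels map to
themselves.

Pairing between gold and predicted items is one-to-one and
**maximum-cardinality**: candidate pairs are seeded greedily in
(descending overlap, ascending gold start, ascending predicted start)
order and completed by augmenting paths. A plain greedy pass is not
maximal on chains of partially overlapping relaxed matches (gold
[0,5),[5,20) against predictions [3,15),[15,30) pairs only one item
greedily but two maximally), and maximality is what makes the TP count
well-defined, order-independent, and provably monotone: loosening the
span mode or the label level can only add candidate edges, so
F(relaxed) ≥ F(exact) and F(high) ≥ F(fine) hold structurally. Only the
pairing cardinality affects any reported number, so the tie-break order
influences nothing observable.

Micro-averaging pools TP/FP/FN over all snippets before computing
P/R/F1. Degenerate conventions: P = 0 with no predictions, R = 0 with no
gold, and vacuous perfection (P = R = F1 = 1) when both sides are empty —
this keeps self-scoring exactly 1 on every corpus. Predictions whose
snippet keys are absent from gold raise an error rather than being
silently dropped.

Events are relation instances expanded to (role, trigger label+span,
argument label+span); duplicates within one file are deduplicated with a
warning before scoring. Two events match iff roles are equal and both
endpoints match as entities under the active criterion.

The confusion matrix is computed under exact span matching: each gold
annotation seeks an unused predicted annotation with the identical
fragment list (preferring one with the same label); absent counterparts
are booked against NEG. Both the NEG/NEG cell and cross-label row/column
conservation are structural.

Cohen's kappa uses the union of exact spans annotated by at least one
annotator as its unit set; an annotator's assignment on a unit is its
label or NONE. Expected agreement is the dot product of the two
annotators' marginal distributions. Exact-span units were chosen (over
relaxed-overlap clusters) because they make the unit set and the NONE
assignment unambiguous; pairwise F1 covers span-tolerant agreement.

## The co-occurrence baseline

Tokenization: a token is a contiguous block of letters/digits or a single
punctuation mark. Sentence splitting is rule-based: split after `.?!`
followed by whitespace and an uppercase letter or digit, and at blank
lines, guarded by an abbreviation list (`e.g.`, `ca.`, `approx.`, …) and a
single-letter+period rule that keeps temperature expressions such as
`80° C.` intact. The splitter is deterministic and dependency-free, which
matters more here than linguistic finesse: its only consumer is the
sentence co-occurrence window.

`D_e` maps each annotated trigger surface to its most frequent label;
ties prefer the label with the higher corpus-wide trigger count, then the
lexicographically smaller label. Keys are matched case-sensitively by
default (a `lowercase` option exists) and may span multiple tokens;
spotting is left-to-right, longest-match-first, non-overlapping. A
trigger crossing a sentence boundary belongs to the sentence containing
its start offset. `D_r` holds every observed ⟨role, trigger label,
entity label⟩ triple; prediction emits one relation per licensed role for
every same-sentence trigger–entity pair. The end-to-end composition
accepts any NER system's annotations as the entity stage.

## Leakage analyses

Bag-of-words vectors are raw lowercased token counts — no binarization,
no tf-idf — and similarity is plain cosine. A test snippet's leakage
score is its maximum similarity over training snippets, binned Q1
[0, 0.25) through Q4 [0.75, 1.0]. Only the training split feeds the
comparison by default; the development split can be merged in by the
caller (the CLI's `--dev` flag does this for entropy, and concatenating
corpora does it for similarity).

Entity entropy applies E(e) = −Σ pᵢ log₁₀ pᵢ **literally, without
normalization**, over the surface form's counts across the ten entity
labels plus "O". The two published worked distributions (125/66/37/11/10
→ 0.542 and 261/123/42/6 → 0.412) confirm the unnormalized base-10 form.
With all eleven categories occupied the formula can exceed 1.0 (up to
log₁₀ 11 ≈ 1.041) even though the stated range is [0, 1]; rather than
guessing a normalization, values ≥ 1.0 are binned into S4 together with
the unseen surfaces that are assigned E = 1.0 by convention.

Surface-form identity is case-insensitive with internal whitespace
collapsed. "O" counts are token-boundary-aligned, non-overlapping
occurrences of the surface in raw training(+dev) text not covered by any
entity annotation; trigger surfaces are excluded from the profile (the
analysis concerns entities), but an entity surface inside a trigger span
still counts as "O". In stratified scoring, TP/FN attach to the gold
entity's bin and FP to the predicted entity's bin, with the predicted
surface's entropy computed on the fly from the same profile — so per-bin
TP+FN sums exactly to the gold entity count.

Grouped subsetting returns the test snippets whose source-document id
appears in neither train nor dev; it errors on missing group ids rather
than guessing.

## The synthetic generator

The generator emulates only the structural features the algorithms
consume: labeled spans, trigger words, clause-scoped relations, sentence
boundaries, surface reuse across labels, near-duplicate snippets, and
source-document grouping. It does not attempt real chemical nomenclature,
IUPAC names, or natural prose — fixtures are deterministic templates, so
passing tests demonstrate correctness of the *evaluation machinery*, not
performance of any extraction system on real patents.

Default conditions: label proportions follow the reference per-label
instance counts (so OTHER_COMPOUND ≈ 20%, REACTION_STEP ≈ 16%, …);
snippets hold 2–6 sentences (median 4); snippets cluster into synthetic
source documents of ~8 snippets. Each sentence holds one clause, or two
with probability 0.4; each clause has one trigger (label drawn from the
trigger proportions) and on average p(entities)/p(triggers) ≈ 2.4
entities (labels drawn from the entity proportions), so the overall label
mix converges to the configuration (within 0.02 by ~5,000 annotations).
Gold relations are **clause-scoped** while the baseline's rule is
**sentence-scoped**; two-clause sentences are therefore exactly what
makes the baseline over-generate and reproduces its high-recall,
low-precision profile.

`ambiguity_rate` (default 0.1) is the probability that a compound or
trigger surface is drawn from a pool shared across labels, and (at half
that rate) that a clause carries an unannotated compound mention — both
feed non-zero entropies and the "O" category. At rate 0 every surface is
label-unique and all profile entropies are exactly 0. `overlap_rate`
(default 0.1) re-renders an earlier snippet's template with ~30% of
entity surfaces redrawn, producing the near-duplicates that populate Q4.
Randomness is derived per snippet from a string-hashed root seed, so
output is byte-identical under a fixed seed and adding snippets does not
shift earlier ones.

Perturbation applies at most one of deletion / label swap / span shift
per annotation (rates are exclusive probabilities) plus insertions on
unannotated token spans, and keeps every produced span distinct from all
gold spans and from each other, whitespace-trimmed, and overlapping its
original (for shifts). These constraints make the ledger an exact oracle
under exact matching: FN = deletions + swaps + shifts,
FP = insertions + swaps + shifts, confusion off-diagonals = the swap
counts. Swaps favor the hardest real-world confusions (starting material
↔ reagent/catalyst, product ↔ other compound, solvent ↔
reagent/catalyst) with probability 0.8. If no legal shift exists after 20
draws the annotation is left unchanged and nothing is booked.

Splitting uses largest-remainder rounding (1,500 snippets at
0.6/0.15/0.25 gives exactly 900/225/375); the group-aware mode assigns
whole groups, largest first, to the split with the largest remaining
deficit, guaranteeing zero group sharing. Every split result carries a
label-distribution comparison across the three parts.

## Problem sizes used in the test suite

The suite runs the matching oracle on 1,000+ random instances of ≤6×6
annotations, perturbation-ledger recovery over 20 seeds × 15 snippets,
baseline rule equivalence over 100+ snippets and its recall profile over
seeds 1–10 × 60 snippets, and split arithmetic at 1,500 snippets — sizes
chosen so the whole suite completes in seconds while every property is
exercised at a scale where violations would surface.

## Known limitations

- The sentence splitter guards only a fixed abbreviation list; exotic
  abbreviations may merge sentences. Merged sentences only widen the
  baseline's co-occurrence window (they never remove gold pairs).
- Under relaxed matching a single prediction can never match multiple
  overlapping gold entities: the one-to-one pairing is a deliberate
  choice where the convention is ambiguous, and is documented rather
  than configurable.
- The "O"-count procedure defines occurrence as token-boundary-aligned
  and non-overlapping per surface; alternative definitions (substring
  counts, overlap-tolerant) would shift entropies slightly for surfaces
  that self-overlap.
- The generator's lexical realism is deliberately minimal; results on it
  say nothing about real-patent difficulty, only about scorer and
  baseline correctness.
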