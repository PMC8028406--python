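"""Train/test overlap analyses: similarity bins, entity entropy, grouped subsets.

Three complementary views of how much a test set leaks from training data:

1. **Grouped subsetting** — test snippets whose source document (patent)
   contributes nothing to training form the hardest, leakage-free subset.

2. **Bag-of-words similarity** — each test snippet is represented by its
   raw lowercased token counts; its similarity to the training set is the
   maximum cosine similarity over all training snippets, and test snippets
   are binned into Q1 [0, 0.25), Q2 [0.25, 0.5), Q3 [0.5, 0.75),
   Q4 [0.75, 1.0].

3. **Entity entropy** — for every annotated entity surface form, the label
   distribution over the ten entity labels plus "O" (occurrences in raw
   text not covered by an entity annotation) is collected from the
   training(+development) corpus, and its base-10 Shannon entropy

       E(e) = -sum_i p_i * log10(p_i)

   quantifies how predictable the surface is by pure memorization: 0 means
   one consistent label, larger values mean ambiguity; a surface unseen in
   training is assigned entropy 1.0. Test entities are binned into
   S1 (E = 0), S2 (0 < E < 0.25), S3 (0.25 <= E < 1), S4 (E = 1, incl.
   unseen), and scoring restricted to a bin counts TP/FN over gold
   entities in the bin and FP over predicted entities whose (possibly
   on-the-fly) entropy lands in the bin.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .baseline import tokenize
from .brat import Corpus, EntityAnnotation, Snippet
from .schema import O_LABEL, LabelSchema
from .scoring import MatchCriterion, PRFReport, match_entities

_EPS = 1e-9

Q_BINS = ("Q1", "Q2", "Q3", "Q4")
S_BINS = ("S1", "S2", "S3", "S4")


# ---------------------------------------------------------------------------
# bag-of-words similarity


def bow_vector(text: str) -> Counter:
    """Raw lowercased token counts (no weighting, no binarization)."""
    tokens = [t.surface.lower() for t in tokenize(text)]
    if not tokens:
        raise ValueError("cannot build a bag-of-words vector from empty text")
    return Counter(tokens)


def bow_cosine(a: str, b: str) -> float:
    """Cosine similarity between the raw count vectors of two texts."""
    va, vb = bow_vector(a), bow_vector(b)
    dot = sum(va[t] * vb[t] for t in va.keys() & vb.keys())
    norm = math.sqrt(sum(c * c for c in va.values())) * math.sqrt(
        sum(c * c for c in vb.values())
    )
    return dot / norm


def max_train_similarity(test: Snippet, train: Corpus) -> float:
    """Maximum bag-of-words cosine between a test snippet and any training snippet."""
    if len(train) == 0:
        raise ValueError("training corpus is empty")
    return max(bow_cosine(test.text, s.text) for s in train)


def similarity_bin(value: float) -> str:
    if value < 0.25:
        return "Q1"
    if value < 0.5:
        return "Q2"
    if value < 0.75:
        return "Q3"
    return "Q4"


def similarity_bins(test: Corpus, train: Corpus) -> dict[str, str]:
    """Bin every test snippet key into Q1..Q4 by its max training similarity."""
    return {
        key: similarity_bin(max_train_similarity(snippet, train))
        for key, snippet in test.snippets.items()
    }


@dataclass
class StratumReport:
    """Scores restricted to one similarity or entropy bin."""

    bin_id: str
    boundaries: str
    report: PRFReport
    n_items: int


def stratified_score_by_snippet(
    gold: Corpus,
    pred: Corpus,
    snippet_bins: dict[str, str],
    crit: MatchCriterion,
    schema: LabelSchema,
) -> list[StratumReport]:
    """Per-Q-bin scoring: the corpus-level scorer applied to each bin's snippets."""
    from .scoring import score_ner

    boundaries = {
        "Q1": "[0.00, 0.25)",
        "Q2": "[0.25, 0.50)",
        "Q3": "[0.50, 0.75)",
        "Q4": "[0.75, 1.00]",
    }
    out = []
    for bin_id in Q_BINS:
        keys = [k for k, b in snippet_bins.items() if b == bin_id]
        gold_bin = gold.subset(keys)
        pred_bin = pred.subset([k for k in keys if k in pred.snippets])
        report = (
            score_ner(gold_bin, pred_bin, crit, schema) if keys else PRFReport()
        )
        out.append(
            StratumReport(
                bin_id=bin_id,
                boundaries=boundaries[bin_id],
                report=report,
                n_items=len(keys),
            )
        )
    return out


# ---------------------------------------------------------------------------
# entity entropy


def normalize_surface(surface: str) -> str:
    """Surface-form identity for entropy: case-insensitive, whitespace collapsed."""
    return " ".join(surface.split()).casefold()


def entropy(counts) -> float:
    """Base-10 Shannon entropy of a label-count distribution.

    ``counts`` may be a mapping or a sequence of non-negative counts. An
    all-zero/empty distribution encodes a surface never seen in training
    and is assigned entropy 1.0 (maximally unpredictable by memorization).
    """
    values = list(counts.values()) if hasattr(counts, "values") else list(counts)
    if any(v < 0 for v in values):
        raise ValueError("entropy is undefined for negative counts")
    total = sum(values)
    if total == 0:
        return 1.0
    value = -sum(
        (v / total) * math.log10(v / total) for v in values if v > 0
    )
    return value if value != 0 else 0.0


@dataclass
class EntropyProfile:
    """Per-surface-form label counts over the 10 entity labels plus "O"."""

    counts: dict[str, Counter] = field(default_factory=dict)

    def counts_for(self, surface: str) -> Counter:
        return self.counts.get(normalize_surface(surface), Counter())

    def entropy_of(self, surface: str) -> float:
        """Eq.-style entropy of a surface form; unseen surfaces get 1.0."""
        return entropy(self.counts_for(surface))

    def total_occurrences(self, surface: str) -> int:
        return sum(self.counts_for(surface).values())

    def __len__(self) -> int:
        return len(self.counts)


def build_entropy_profile(train_dev: Corpus, schema: LabelSchema) -> EntropyProfile:
    """Collect the label-count profile of every annotated entity surface form.

    Annotated occurrences contribute to their entity label's count;
    additional occurrences of the same surface form in the raw text —
    token-boundary aligned, non-overlapping, and not covered by any entity
    annotation — contribute to "O". Trigger-word annotations are excluded
    from the profile (the analysis concerns entities only), but an entity
    surface occurring inside a trigger span still counts as "O".
    """
    profile = EntropyProfile()
    for snippet in train_dev:
        for ann in snippet.entities(schema):
            key = normalize_surface(ann.surface)
            profile.counts.setdefault(key, Counter())[ann.label] += 1

    # group profile surfaces by token count for n-gram scanning
    by_n: dict[int, set[str]] = {}
    for key in profile.counts:
        by_n.setdefault(len(key.split()), set()).add(key)

    for snippet in train_dev:
        tokens = tokenize(snippet.text)
        covered = [
            frag for ann in snippet.entities(schema) for frag in ann.fragments
        ]
        last_end: dict[str, int] = {}
        for n, surfaces in by_n.items():
            for i in range(len(tokens) - n + 1):
                start = tokens[i].start
                end = tokens[i + n - 1].end
                key = normalize_surface(snippet.text[start:end])
                if key not in surfaces:
                    continue
                if start < last_end.get(key, 0):
                    continue  # enforce non-overlapping occurrences per surface
                if any(s < end and start < e for s, e in covered):
                    continue
                profile.counts[key][O_LABEL] += 1
                last_end[key] = end
    return profile


def entropy_bin(value: float) -> str:
    """S1: E=0; S2: (0, 0.25); S3: [0.25, 1); S4: E>=1 (incl. unseen surfaces)."""
    if value <= _EPS:
        return "S1"
    if value < 0.25:
        return "S2"
    if value < 1.0 - _EPS:
        return "S3"
    return "S4"


def entropy_bins(
    test_entities: list[EntityAnnotation], profile: EntropyProfile
) -> dict[str, str]:
    """Map each distinct test entity surface form to its S bin."""
    return {
        normalize_surface(ann.surface): entropy_bin(profile.entropy_of(ann.surface))
        for ann in test_entities
    }


def stratified_score(
    gold: Corpus,
    pred: Corpus,
    profile: EntropyProfile,
    crit: MatchCriterion,
    schema: LabelSchema,
) -> list[StratumReport]:
    """Entropy-stratified entity scoring.

    Matching runs once per snippet over all entity annotations; TP and FN
    are then attributed to the bin of the gold entity's surface form, and
    FP to the bin of the predicted entity's surface form — computed on the
    fly from the profile, so a predicted surface never seen in training
    lands in S4. Per-bin (TP + FN) therefore sums to the gold entity count.
    """
    from .scoring import _check_alignment

    _check_alignment(gold, pred)
    boundaries = {
        "S1": "E = 0",
        "S2": "0 < E < 0.25",
        "S3": "0.25 <= E < 1",
        "S4": "E >= 1 or unseen",
    }
    tallies = {b: PRFReport() for b in S_BINS}
    items = Counter()
    for key, gold_snip in gold.snippets.items():
        pred_snip = pred.snippets.get(key)
        gold_ents = gold_snip.entities(schema)
        pred_ents = pred_snip.entities(schema) if pred_snip is not None else []
        pairs, _ = match_entities(gold_ents, pred_ents, crit, schema)
        matched_gold = {id(g) for g, _ in pairs}
        matched_pred = {id(p) for _, p in pairs}

        def bin_of(ann: EntityAnnotation) -> str:
            return entropy_bin(profile.entropy_of(ann.surface))

        for g, _ in pairs:
            b = bin_of(g)
            tallies[b].tp += 1
            tallies[b]._tally(g.label).tp += 1
        for g in gold_ents:
            items[bin_of(g)] += 1
            if id(g) not in matched_gold:
                b = bin_of(g)
                tallies[b].fn += 1
                tallies[b]._tally(g.label).fn += 1
        for p in pred_ents:
            if id(p) not in matched_pred:
                b = bin_of(p)
                tallies[b].fp += 1
                tallies[b]._tally(p.label).fp += 1
    return [
        StratumReport(
            bin_id=b, boundaries=boundaries[b], report=tallies[b], n_items=items[b]
        )
        for b in S_BINS
    ]


# ---------------------------------------------------------------------------
# grouped (source-document) subsetting


def grouped_subset(test: Corpus, train: Corpus, dev: Corpus | None = None) -> Corpus:
    """Test snippets whose source group appears in neither train nor dev."""
    for corpus, name in ((test, "test"), (train, "train")) + (
        ((dev, "dev"),) if dev is not None else ()
    ):
        missing = [s.key for s in corpus if s.group is None]
        if missing:
            raise ValueError(
                f"{name} corpus has snippets without group ids: {missing[:5]}"
            )
    seen = train.groups() | (dev.groups() if dev is not None else set())
    keys = [s.key for s in test if s.group not in seen]
    return test.subset(keys, split="new-groups")
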