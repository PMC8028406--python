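"""Seedable generator of snippet-shaped fixture corpora and controlled
prediction perturbations.

The generator emits corpora with the structural features the evaluation
machinery consumes — labeled spans, trigger words, clause-scoped
trigger->entity relations, sentence boundaries, surface-form reuse across
labels, near-duplicate snippets, and source-document groups — using
deterministic sentence templates rather than any attempt at real
chemistry. Default shape parameters mirror the reference corpus: label
proportions follow its per-label instance counts, snippets hold 2–6
sentences (median 4), and snippets cluster into synthetic source documents
of ~8 snippets each.

A sentence holds one or two *clauses*; each clause contributes one trigger
word plus a few entities, and gold relations link the trigger to the
entities of its own clause (Arg1 for compounds, ArgM for time/temperature/
yield). Because the dictionary co-occurrence baseline windows on whole
sentences, two-clause sentences make it over-generate, reproducing its
high-recall / low-precision profile.

``perturb`` injects span shifts, label swaps, deletions and insertions
into a copy of a gold corpus and returns an exact ledger of what it did;
under exact span matching the scorer's FN/FP and confusion counts must
equal that ledger, which the test suite uses as a bookkeeping oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .brat import Corpus, EntityAnnotation, RelationAnnotation, Snippet, validate_snippet
from .schema import (
    COMPOUND_LABELS,
    CONDITION_LABELS,
    YIELD_LABELS,
    LabelSchema,
)

# Per-label instance counts of the reference corpus, used (normalized) as the
# default span-label sampling proportions.
REFERENCE_LABEL_COUNTS: dict[str, int] = {
    "STARTING_MATERIAL": 2878,
    "REAGENT_CATALYST": 2074,
    "REACTION_PRODUCT": 3413,
    "SOLVENT": 1818,
    "OTHER_COMPOUND": 7651,
    "TIME": 1763,
    "TEMPERATURE": 2473,
    "YIELD_PERCENT": 1572,
    "YIELD_OTHER": 1762,
    "EXAMPLE_LABEL": 1453,
    "REACTION_STEP": 6210,
    "WORKUP": 5026,
}


def default_label_proportions() -> dict[str, float]:
    total = sum(REFERENCE_LABEL_COUNTS.values())
    return {lab: c / total for lab, c in REFERENCE_LABEL_COUNTS.items()}


# ---------------------------------------------------------------------------
# default lexicon: templated pseudo-chemistry surface pools


_PREFIXES = [
    "methyl", "ethyl", "propyl", "butyl", "phenyl", "chloro", "bromo",
    "fluoro", "hydroxy", "amino", "nitro", "cyclo", "benzo", "oxo", "thio",
]
_SUFFIXES = [
    "benzene", "acetate", "aniline", "pyridine", "amide", "acetic acid",
    "ether", "oxide", "sulfate", "amine", "phenol", "ketone", "ester",
    "chloride", "carbamate",
]


def _compound_pool(tag: int, size: int) -> list[str]:
    """A deterministic, label-specific slice of prefix x suffix combinations."""
    pool = []
    for i in range(size):
        p = _PREFIXES[(tag * 7 + i * 3) % len(_PREFIXES)]
        s = _SUFFIXES[(tag * 5 + i) % len(_SUFFIXES)]
        pool.append(f"{p}{s}" if " " not in s else f"{p} {s}")
    return list(dict.fromkeys(pool))


def default_lexicon() -> dict[str, list[str]]:
    """Surface pools per span label; pools are label-disjoint by construction."""
    lex = {
        lab: _compound_pool(tag, 12)
        for tag, lab in enumerate(COMPOUND_LABELS)
    }
    lex["TIME"] = ["2 hours", "30 minutes", "16 hours", "overnight", "45 minutes", "3 days"]
    lex["TEMPERATURE"] = ["25° C.", "0° C.", "80° C.", "reflux", "-78° C.", "110° C.", "room temperature"]
    lex["YIELD_PERCENT"] = ["85%", "92%", "47%", "63%", "71%", "99%"]
    lex["YIELD_OTHER"] = ["1.2 g", "450 mg", "0.8 g", "2.4 g", "310 mg", "5.1 g"]
    lex["EXAMPLE_LABEL"] = [str(i) for i in range(1, 25)] + ["1a", "2b", "3c"]
    lex["REACTION_STEP"] = [
        "stirred", "heated", "refluxed", "treated", "reacted", "combined",
        "hydrogenated", "condensed",
    ]
    lex["WORKUP"] = [
        "washed", "filtered", "concentrated", "dried", "extracted",
        "purified", "evaporated", "recrystallized",
    ]
    return lex


#: surfaces deliberately shared between compound labels / trigger labels
_AMBIGUOUS_COMPOUNDS = [
    "methanol", "ethanol", "water", "acetone", "toluene", "brine",
    "hexane", "dioxane",
]
_AMBIGUOUS_TRIGGERS = ["added", "cooled", "warmed", "quenched"]

_OPENERS = [
    "The mixture was",
    "The solution was",
    "The residue was",
    "The crude product was",
    "The reaction was then",
]
_COMPOUND_CONNECTORS = ["with", "into", "together with", "using"]


@dataclass
class GeneratorConfig:
    """Study conditions for fixture corpora.

    ``label_proportions`` defaults to the reference corpus's per-label
    instance counts (normalized); ``ambiguity_rate`` is the probability
    that a compound/trigger surface is drawn from a pool shared across
    labels (and that sentences carry unannotated entity-surface mentions,
    feeding the "O" entropy category); ``overlap_rate`` is the probability
    a snippet re-renders an earlier snippet's template, creating
    near-duplicates that populate the high-similarity Q bins.
    """

    seed: int = 0
    n_snippets: int = 50
    label_proportions: dict[str, float] = field(default_factory=default_label_proportions)
    sentences_per_snippet: tuple[int, int] = (2, 6)
    lexicon: dict[str, list[str]] = field(default_factory=default_lexicon)
    ambiguity_rate: float = 0.1
    overlap_rate: float = 0.1
    group_count: int | None = None  # default: ~8 snippets per group

    def validate(self, schema: LabelSchema) -> None:
        if self.n_snippets < 1:
            raise ValueError("n_snippets must be positive")
        if abs(sum(self.label_proportions.values()) - 1.0) > 1e-6:
            raise ValueError("label_proportions must sum to 1")
        for rate in (self.ambiguity_rate, self.overlap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.sentences_per_snippet
        if not (1 <= lo <= hi):
            raise ValueError("sentences_per_snippet must be a valid range")
        for lab, p in self.label_proportions.items():
            if p > 0 and not self.lexicon.get(lab):
                raise ValueError(f"empty lexicon for requested label {lab!r}")

    def resolved_group_count(self) -> int:
        if self.group_count is not None:
            return self.group_count
        return max(1, round(self.n_snippets / 8))


# ---------------------------------------------------------------------------
# snippet assembly


class _SnippetBuilder:
    """Accumulates literal text and annotated spans with running offsets."""

    def __init__(self, key: str, group: str | None) -> None:
        self.key = key
        self.group = group
        self.parts: list[str] = []
        self.pos = 0
        self.annotations: list[EntityAnnotation] = []
        self.relations: list[RelationAnnotation] = []

    def literal(self, text: str) -> None:
        self.parts.append(text)
        self.pos += len(text)

    def span(self, surface: str, label: str) -> EntityAnnotation:
        ann = EntityAnnotation(
            id=f"T{len(self.annotations) + 1}",
            label=label,
            fragments=((self.pos, self.pos + len(surface)),),
            surface=surface,
        )
        self.annotations.append(ann)
        self.literal(surface)
        return ann

    def relation(self, role: str, trigger: EntityAnnotation, arg: EntityAnnotation) -> None:
        self.relations.append(
            RelationAnnotation(
                id=f"R{len(self.relations) + 1}",
                role=role,
                trigger_id=trigger.id,
                arg_id=arg.id,
            )
        )

    def build(self) -> Snippet:
        return Snippet(
            key=self.key,
            text="".join(self.parts),
            annotations=self.annotations,
            relations=self.relations,
            group=self.group,
        )


# a snippet "plan" is re-renderable, which is how near-duplicates are made:
# plan := list of sentences; sentence := list of clauses;
# clause := (opener, trigger (surface,label), entities [(connector, label, surface)],
#            o_mention or None)
Clause = tuple[str, tuple[str, str], list[tuple[str, str, str]], str | None]


def _choose_surface(
    rng: random.Random, label: str, config: GeneratorConfig, schema: LabelSchema
) -> str:
    ambiguous_pool = None
    if label in COMPOUND_LABELS:
        ambiguous_pool = _AMBIGUOUS_COMPOUNDS
    elif label in schema.trigger_labels:
        ambiguous_pool = _AMBIGUOUS_TRIGGERS
    if ambiguous_pool and rng.random() < config.ambiguity_rate:
        return rng.choice(ambiguous_pool)
    return rng.choice(config.lexicon[label])


def _entity_connector(rng: random.Random, label: str) -> str:
    if label in COMPOUND_LABELS:
        return rng.choice(_COMPOUND_CONNECTORS)
    if label == "TIME":
        return "for"
    if label == "TEMPERATURE":
        return "at"
    if label == "YIELD_PERCENT":
        return "in a yield of"
    if label == "YIELD_OTHER":
        return "giving"
    return "as in step"  # EXAMPLE_LABEL


def _plan_snippet(
    rng: random.Random, config: GeneratorConfig, schema: LabelSchema
) -> list[list[Clause]]:
    props = config.label_proportions
    trigger_labels = [l for l in schema.trigger_labels if props.get(l, 0) > 0]
    entity_labels = [l for l in schema.entity_labels if props.get(l, 0) > 0]
    p_trig = sum(props[l] for l in trigger_labels)
    p_ent = sum(props[l] for l in entity_labels)
    if p_trig <= 0:
        raise ValueError("generator requires nonzero trigger proportions")
    # expected entities per trigger so that the overall label mix is respected
    ratio = p_ent / p_trig
    trig_weights = [props[l] for l in trigger_labels]
    ent_weights = [props[l] for l in entity_labels]

    n_sent = rng.randint(*config.sentences_per_snippet)
    plan: list[list[Clause]] = []
    for _ in range(n_sent):
        n_clauses = 2 if rng.random() < 0.4 else 1
        sentence: list[Clause] = []
        for _ in range(n_clauses):
            opener = rng.choice(_OPENERS)
            trig_label = rng.choices(trigger_labels, weights=trig_weights)[0]
            trig_surface = _choose_surface(rng, trig_label, config, schema)
            m = int(ratio) + (1 if rng.random() < ratio - int(ratio) else 0)
            m = max(1, m)
            entities = []
            for _ in range(m):
                ent_label = rng.choices(entity_labels, weights=ent_weights)[0]
                surface = _choose_surface(rng, ent_label, config, schema)
                entities.append((_entity_connector(rng, ent_label), ent_label, surface))
            o_mention = None
            if rng.random() < config.ambiguity_rate / 2:
                pool_label = rng.choice(COMPOUND_LABELS)
                o_mention = _choose_surface(rng, pool_label, config, schema)
            sentence.append((opener, (trig_surface, trig_label), entities, o_mention))
        plan.append(sentence)
    return plan


def _mutate_plan(
    rng: random.Random,
    plan: list[list[Clause]],
    config: GeneratorConfig,
    schema: LabelSchema,
) -> list[list[Clause]]:
    """Re-render an existing plan with a few entity surfaces redrawn.

    Keeps openers, connectors, triggers and structure, so the resulting
    snippet is lexically very close to its template snippet.
    """
    mutated: list[list[Clause]] = []
    for sentence in plan:
        new_sentence: list[Clause] = []
        for opener, trig, entities, o_mention in sentence:
            new_entities = []
            for connector, label, surface in entities:
                if rng.random() < 0.3:
                    surface = _choose_surface(rng, label, config, schema)
                new_entities.append((connector, label, surface))
            new_sentence.append((opener, trig, new_entities, o_mention))
        mutated.append(new_sentence)
    return mutated


def _render_plan(
    builder: _SnippetBuilder, plan: list[list[Clause]]
) -> None:
    for si, sentence in enumerate(plan):
        if si:
            builder.literal(" ")
        for ci, (opener, (trig_surface, trig_label), entities, o_mention) in enumerate(
            sentence
        ):
            if ci:
                builder.literal(", and then ")
                builder.literal(opener[0].lower() + opener[1:] + " ")
            else:
                builder.literal(opener + " ")
            trig_ann = builder.span(trig_surface, trig_label)
            for connector, label, surface in entities:
                builder.literal(f" {connector} ")
                ent_ann = builder.span(surface, label)
                role = "Arg1" if label in COMPOUND_LABELS else (
                    None if label == "EXAMPLE_LABEL" else "ArgM"
                )
                if role is not None:
                    builder.relation(role, trig_ann, ent_ann)
            if o_mention is not None:
                builder.literal(f" in the presence of {o_mention}")
        builder.literal(".")


def generate(config: GeneratorConfig, schema: LabelSchema | None = None) -> Corpus:
    """Generate a validated fixture corpus under the configured conditions."""
    schema = schema or LabelSchema.default()
    config.validate(schema)
    corpus = Corpus(split="none")
    group_count = config.resolved_group_count()
    plans: list[list[list[Clause]]] = []
    for i in range(config.n_snippets):
        rng = random.Random(f"{config.seed}:snippet:{i}")
        key = f"synth{i:04d}"
        group = f"patent{rng.randrange(group_count):03d}"
        if plans and rng.random() < config.overlap_rate:
            plan = _mutate_plan(rng, rng.choice(plans), config, schema)
        else:
            plan = _plan_snippet(rng, config, schema)
        plans.append(plan)
        builder = _SnippetBuilder(key, group)
        _render_plan(builder, plan)
        snippet = builder.build()
        validate_snippet(snippet, schema)
        corpus.add(snippet)
    return corpus


# ---------------------------------------------------------------------------
# perturbation


@dataclass
class PerturbationSpec:
    """Error-injection rates for building controlled prediction corpora.

    ``swap_pairs`` lists the label confusions favored when swapping —
    defaults follow the hardest distinctions observed in real systems
    (starting material vs. reagent/catalyst, product vs. other compound,
    solvent vs. reagent/catalyst).
    """

    span_shift_rate: float = 0.0
    label_swap_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    swap_pairs: tuple[tuple[str, str], ...] = (
        ("STARTING_MATERIAL", "REAGENT_CATALYST"),
        ("REACTION_PRODUCT", "OTHER_COMPOUND"),
        ("SOLVENT", "REAGENT_CATALYST"),
    )

    def validate(self) -> None:
        rates = (
            self.span_shift_rate,
            self.label_swap_rate,
            self.deletion_rate,
            self.insertion_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("perturbation rates must lie in [0, 1]")
        if sum(rates[:3]) > 1.0:
            raise ValueError(
                "deletion + swap + shift rates must not exceed 1 (mutually exclusive per annotation)"
            )


@dataclass
class PerturbationLedger:
    """Exact bookkeeping of the edits applied to a gold corpus."""

    deletions: int = 0
    label_swaps: int = 0
    span_shifts: int = 0
    insertions: int = 0
    dropped_relations: int = 0
    swap_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def record_swap(self, old: str, new: str) -> None:
        self.label_swaps += 1
        self.swap_counts[(old, new)] = self.swap_counts.get((old, new), 0) + 1

    def to_json_dict(self) -> dict:
        return {
            "deletions": self.deletions,
            "label_swaps": self.label_swaps,
            "span_shifts": self.span_shifts,
            "insertions": self.insertions,
            "dropped_relations": self.dropped_relations,
            "swap_counts": {f"{a}->{b}": c for (a, b), c in sorted(self.swap_counts.items())},
        }


def _swap_target(
    rng: random.Random, label: str, spec: PerturbationSpec, schema: LabelSchema
) -> str:
    favored = [
        b if a == label else a
        for a, b in spec.swap_pairs
        if label in (a, b)
    ]
    if favored and rng.random() < 0.8:
        return rng.choice(favored)
    pool = (
        [l for l in schema.entity_labels if l != label]
        if schema.is_entity(label)
        else [l for l in schema.trigger_labels if l != label]
    )
    return rng.choice(pool)


def _shift_fragments(
    rng: random.Random,
    ann: EntityAnnotation,
    text: str,
    forbidden: set[tuple],
) -> tuple[tuple[int, int], ...] | None:
    """A shifted fragment list: valid, distinct from the original, still
    overlapping it, whitespace-free at its edges, and not colliding with
    any forbidden span."""
    text_len = len(text)
    for _ in range(20):
        fragments = list(ann.fragments)
        idx = rng.randrange(len(fragments))
        s, e = fragments[idx]
        ds = rng.choice((-2, -1, 0, 1, 2))
        de = rng.choice((-2, -1, 0, 1, 2))
        ns, ne = s + ds, e + de
        if (ns, ne) == (s, e) or not (0 <= ns < ne <= text_len):
            continue
        if ne <= s or ns >= e:  # must still overlap the original
            continue
        if text[ns].isspace() or text[ne - 1].isspace():
            continue
        fragments[idx] = (ns, ne)
        frags = tuple(fragments)
        if any(f1[1] > f2[0] for f1, f2 in zip(frags, frags[1:])):
            continue
        if frags in forbidden:
            continue
        return frags
    return None


def perturb(
    gold: Corpus,
    spec: PerturbationSpec,
    seed: int,
    schema: LabelSchema | None = None,
) -> tuple[Corpus, PerturbationLedger]:
    """Apply controlled errors to a copy of ``gold`` and return the exact ledger.

    Per annotation, at most one of deletion / label swap / span shift is
    applied (rates are exclusive probabilities); insertions add spurious
    annotations on unannotated token spans. All resulting spans are kept
    distinct from every gold span and from each other, so that under exact
    span matching the scorer's FN equals deletions + swaps + shifts, FP
    equals insertions + swaps + shifts, and confusion off-diagonals equal
    the swap counts. Relations whose endpoints were deleted are dropped.
    """
    from .baseline import tokenize

    schema = schema or LabelSchema.default()
    spec.validate()
    ledger = PerturbationLedger()
    pred = Corpus(split="pred")
    for key, snippet in gold.snippets.items():
        rng = random.Random(f"{seed}:perturb:{key}")
        gold_spans = {a.fragments for a in snippet.annotations}
        taken_spans = set(gold_spans)
        new_anns: list[EntityAnnotation] = []
        surviving: dict[str, str] = {}  # gold id -> pred id (unchanged span ids)
        deleted_ids: set[str] = set()
        for ann in snippet.annotations:
            u = rng.random()
            if u < spec.deletion_rate:
                ledger.deletions += 1
                deleted_ids.add(ann.id)
                continue
            u -= spec.deletion_rate
            if u < spec.label_swap_rate:
                new_label = _swap_target(rng, ann.label, spec, schema)
                ledger.record_swap(ann.label, new_label)
                new_anns.append(replace(ann, label=new_label))
                surviving[ann.id] = ann.id
                continue
            u -= spec.label_swap_rate
            if u < spec.span_shift_rate:
                frags = _shift_fragments(rng, ann, snippet.text, taken_spans)
                if frags is None:
                    # no legal shift found; keep the annotation unchanged
                    new_anns.append(ann)
                    surviving[ann.id] = ann.id
                    continue
                ledger.span_shifts += 1
                deleted_ids.add(ann.id)  # relations to shifted spans are kept
                taken_spans.add(frags)
                from .brat import expected_surface

                new_anns.append(
                    replace(
                        ann,
                        fragments=frags,
                        surface=expected_surface(snippet.text, frags),
                    )
                )
                surviving[ann.id] = ann.id
                deleted_ids.discard(ann.id)
                continue
            new_anns.append(ann)
            surviving[ann.id] = ann.id

        # insertions: spurious annotations on unannotated token spans
        n_insert = sum(
            rng.random() < spec.insertion_rate for _ in snippet.annotations
        )
        tokens = tokenize(snippet.text)
        attempts = 0
        inserted = 0
        while inserted < n_insert and attempts < 50 * max(1, n_insert):
            attempts += 1
            if not tokens:
                break
            i = rng.randrange(len(tokens))
            n = rng.choice((1, 2))
            if i + n > len(tokens):
                continue
            frags = ((tokens[i].start, tokens[i + n - 1].end),)
            if frags in taken_spans:
                continue
            label = rng.choice(schema.span_labels)
            taken_spans.add(frags)
            new_anns.append(
                EntityAnnotation(
                    id=f"TI{inserted + 1}",
                    label=label,
                    fragments=frags,
                    surface=snippet.text[frags[0][0] : frags[0][1]],
                )
            )
            inserted += 1
        ledger.insertions += inserted

        new_rels = []
        for rel in snippet.relations:
            if rel.trigger_id in deleted_ids or rel.arg_id in deleted_ids:
                ledger.dropped_relations += 1
                continue
            trig_label = next(a.label for a in new_anns if a.id == rel.trigger_id)
            if not schema.is_trigger(trig_label):
                # a label swap turned the trigger into an entity; drop the relation
                ledger.dropped_relations += 1
                continue
            arg_label = next(a.label for a in new_anns if a.id == rel.arg_id)
            if not schema.is_entity(arg_label):
                ledger.dropped_relations += 1
                continue
            new_rels.append(rel)
        pred_snippet = Snippet(
            key=key,
            text=snippet.text,
            annotations=new_anns,
            relations=new_rels,
            group=snippet.group,
        )
        validate_snippet(pred_snippet, schema)
        pred.add(pred_snippet)
    return pred, ledger


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitResult:
    train: Corpus
    dev: Corpus
    test: Corpus
    distribution_report: dict[str, dict[str, float]]
    max_fluctuation: float


def _largest_remainder_sizes(n: int, ratios: tuple[float, float, float]) -> list[int]:
    raw = [n * r for r in ratios]
    sizes = [int(x) for x in raw]
    remainder = n - sum(sizes)
    order = sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split(
    corpus: Corpus,
    ratios: tuple[float, float, float] = (0.6, 0.15, 0.25),
    seed: int = 0,
    group_aware: bool = False,
    schema: LabelSchema | None = None,
) -> SplitResult:
    """Randomly partition a corpus into train/dev/test with largest-remainder sizing.

    With ``group_aware`` every source group lands entirely in one split
    (groups are assigned, largest first, to the split with the largest
    remaining deficit). The result carries a label-distribution comparison
    across the splits and its maximum per-label fluctuation.
    """
    schema = schema or LabelSchema.default()
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ValueError("split ratios must be non-negative and sum to 1")
    keys = sorted(corpus.snippets)
    rng = random.Random(f"{seed}:split")
    sizes = _largest_remainder_sizes(len(keys), ratios)
    buckets: list[list[str]] = [[], [], []]
    if not group_aware:
        rng.shuffle(keys)
        buckets[0] = keys[: sizes[0]]
        buckets[1] = keys[sizes[0] : sizes[0] + sizes[1]]
        buckets[2] = keys[sizes[0] + sizes[1] :]
    else:
        by_group: dict[str, list[str]] = {}
        for key in keys:
            group = corpus.snippets[key].group
            if group is None:
                raise ValueError(f"group-aware split requires group ids ({key} has none)")
            by_group.setdefault(group, []).append(key)
        groups = sorted(by_group, key=lambda g: (-len(by_group[g]), g))
        rng.shuffle(groups)
        groups.sort(key=lambda g: -len(by_group[g]))
        deficits = list(sizes)
        for group in groups:
            i = max(range(3), key=lambda j: deficits[j])
            buckets[i].extend(by_group[group])
            deficits[i] -= len(by_group[group])
    parts = [
        corpus.subset(sorted(bucket), split=name)
        for bucket, name in zip(buckets, ("train", "dev", "test"))
    ]

    from .brat import label_distribution

    distributions = {
        part.split: (label_distribution(part, schema) if len(part) else {})
        for part in parts
    }
    fluctuation = 0.0
    for lab in schema.span_labels:
        values = [d.get(lab, 0.0) for d in distributions.values() if d]
        if len(values) > 1:
            fluctuation = max(fluctuation, max(values) - min(values))
    return SplitResult(
        train=parts[0],
        dev=parts[1],
        test=parts[2],
        distribution_report=distributions,
        max_fluctuation=fluctuation,
    )
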