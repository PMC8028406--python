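"""Dictionary co-occurrence baseline for event extraction.

The baseline learns two dictionaries from an annotated training corpus:

* ``D_e`` maps each observed trigger-word surface form to its most
  frequent trigger label (REACTION_STEP or WORKUP);
* ``D_r`` is the set of (role, trigger label, entity label) triples
  observed among gold events, e.g. ``(Arg1, WORKUP, OTHER_COMPOUND)``.

At prediction time, triggers are spotted by dictionary lookup over the
token stream (longest match first, left to right, non-overlapping), and an
event is emitted for every trigger–entity pair that (1) co-occurs in the
same sentence and (2) whose (role, trigger label, entity label) triple is
licensed by ``D_r``. The method deliberately over-generates — every
licensed pair in the sentence window is emitted — so its recall is high
and its precision low.

Tokenization follows the convention of the upstream NER baseline: a token
is either a contiguous block of letters and/or digits or a single
punctuation mark. The sentence splitter is rule-based (see
:func:`split_sentences`).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .brat import Corpus, EntityAnnotation, RelationAnnotation, Snippet
from .schema import LabelSchema

# contiguous letters/digits, or any single non-space character
_TOKEN_RE = re.compile(r"[^\W_]+|\S", re.UNICODE)


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str


def tokenize(text: str) -> list[Token]:
    """Split text into letter/digit blocks and single punctuation marks.

    Tokens cover every non-whitespace character; offsets index the
    original string, so joining token surfaces with the original gaps
    reconstructs the input.
    """
    return [
        Token(m.start(), m.end(), m.group())
        for m in _TOKEN_RE.finditer(text)
    ]


# sentence terminators followed by whitespace then an uppercase letter or digit
_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s)")
_BLANK_LINE_RE = re.compile(r"\n[ \t]*\n")

#: abbreviations after which a period never ends a sentence
ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "ca", "approx", "etc", "cf", "vs", "eq", "fig", "no", "al"}
)


def _is_guarded(text: str, period_pos: int) -> bool:
    """True if the terminator at ``period_pos`` ends a known abbreviation
    or a single-letter abbreviation like the temperature unit in "80° C."."""
    m = re.search(r"([A-Za-z][A-Za-z.]*)\.$", text[: period_pos + 1])
    if m is None:
        return False
    word = m.group(1)
    if len(word) == 1:
        return True
    return word.rstrip(".").lower() in ABBREVIATIONS or word.lower() in ABBREVIATIONS


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence segmentation returning half-open char intervals.

    Splits after a run of ``.?!`` followed by whitespace and an uppercase
    letter or digit (with an abbreviation guard), and at blank lines. The
    returned intervals are trimmed of surrounding whitespace and cover all
    non-whitespace text.
    """
    cut_points: set[int] = set()
    for m in _BOUNDARY_RE.finditer(text):
        after = m.end()
        rest = text[after:].lstrip()
        if not rest:
            continue
        if not (rest[0].isupper() or rest[0].isdigit()):
            continue
        if _is_guarded(text, m.end() - 1):
            continue
        cut_points.add(after)
    for m in _BLANK_LINE_RE.finditer(text):
        cut_points.add(m.start())

    intervals: list[tuple[int, int]] = []
    start = 0
    for cut in sorted(cut_points) + [len(text)]:
        piece = text[start:cut]
        lead = len(piece) - len(piece.lstrip())
        trail = len(piece) - len(piece.rstrip())
        if piece.strip():
            intervals.append((start + lead, cut - trail))
        start = cut
    return intervals


def sentence_index(seg: list[tuple[int, int]], offset: int) -> int:
    """Index of the sentence whose interval contains ``offset``.

    An annotation crossing a sentence boundary belongs to the sentence
    containing its start offset; offsets in inter-sentence whitespace
    attach to the preceding sentence.
    """
    for i, (s, e) in enumerate(seg):
        if s <= offset < e:
            return i
    for i in range(len(seg) - 1, -1, -1):
        if seg[i][0] <= offset:
            return i
    return 0


# ---------------------------------------------------------------------------
# dictionaries


def _normalize_key(surface: str, lowercase: bool) -> str:
    key = " ".join(surface.split())
    return key.lower() if lowercase else key


@dataclass
class TriggerDictionary:
    """Trigger surface form -> per-label observation counts (``D_e``).

    ``label_for`` resolves each surface to its most frequent label; ties
    prefer the label with the higher corpus-wide trigger count, then the
    lexicographically smaller label.
    """

    counts: dict[str, Counter] = field(default_factory=dict)
    label_totals: Counter = field(default_factory=Counter)
    lowercase: bool = False

    def observe(self, surface: str, label: str) -> None:
        key = _normalize_key(surface, self.lowercase)
        self.counts.setdefault(key, Counter())[label] += 1
        self.label_totals[label] += 1

    def label_for(self, surface: str) -> str | None:
        key = _normalize_key(surface, self.lowercase)
        per_label = self.counts.get(key)
        if not per_label:
            return None
        return min(
            per_label,
            key=lambda lab: (-per_label[lab], -self.label_totals[lab], lab),
        )

    def __len__(self) -> int:
        return len(self.counts)

    def max_key_tokens(self) -> int:
        return max((len(k.split()) for k in self.counts), default=0)


@dataclass
class RelationDictionary:
    """Set of observed (role, trigger label, entity label) triples (``D_r``)."""

    triples: set[tuple[str, str, str]] = field(default_factory=set)

    def add(self, role: str, trigger_label: str, entity_label: str) -> None:
        self.triples.add((role, trigger_label, entity_label))

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return triple in self.triples

    def __len__(self) -> int:
        return len(self.triples)


def build_dictionaries(
    train: Corpus, schema: LabelSchema, lowercase: bool = False
) -> tuple[TriggerDictionary, RelationDictionary]:
    """Collect ``D_e`` and ``D_r`` from the gold triggers and events of a corpus."""
    if len(train) == 0:
        raise ValueError("cannot build baseline dictionaries from an empty corpus")
    d_e = TriggerDictionary(lowercase=lowercase)
    d_r = RelationDictionary()
    for snippet in train:
        by_id = {a.id: a for a in snippet.annotations}
        for ann in snippet.annotations:
            if schema.is_trigger(ann.label):
                d_e.observe(ann.surface, ann.label)
        for rel in snippet.relations:
            trig = by_id[rel.trigger_id]
            arg = by_id[rel.arg_id]
            d_r.add(rel.role, trig.label, arg.label)
    return d_e, d_r


# ---------------------------------------------------------------------------
# prediction


def predict_triggers(
    snippet: Snippet, d_e: TriggerDictionary
) -> list[EntityAnnotation]:
    """Spot trigger words via dictionary lookup over the token stream.

    The scan is left-to-right and longest-match-first over token
    n-grams, and emitted triggers never overlap.
    """
    if len(d_e) == 0:
        raise ValueError("trigger dictionary is empty")
    tokens = tokenize(snippet.text)
    max_n = d_e.max_key_tokens()
    out: list[EntityAnnotation] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            start = tokens[i].start
            end = tokens[i + n - 1].end
            surface = snippet.text[start:end]
            label = d_e.label_for(surface)
            if label is not None:
                hit = (start, end, surface, label, n)
                break
        if hit is None:
            i += 1
            continue
        start, end, surface, label, n = hit
        out.append(
            EntityAnnotation(
                id=f"T{len(out) + 1}",
                label=label,
                fragments=((start, end),),
                surface=surface,
            )
        )
        i += n
    return out


def predict_events(
    snippet: Snippet,
    entities: list[EntityAnnotation],
    triggers: list[EntityAnnotation],
    d_r: RelationDictionary,
    seg: list[tuple[int, int]] | None = None,
) -> list[RelationAnnotation]:
    """Emit every relation licensed by sentence co-occurrence and ``D_r``.

    For each trigger–entity pair whose spans fall in the same sentence and
    each role whose (role, trigger label, entity label) triple is in
    ``D_r``, one relation is produced.
    """
    if seg is None:
        seg = split_sentences(snippet.text)
    relations: list[RelationAnnotation] = []
    ordered_triggers = sorted(triggers, key=lambda a: (a.start, a.end))
    ordered_entities = sorted(entities, key=lambda a: (a.start, a.end))
    for trig in ordered_triggers:
        trig_sent = sentence_index(seg, trig.start)
        for ent in ordered_entities:
            if sentence_index(seg, ent.start) != trig_sent:
                continue
            for role in ("Arg1", "ArgM"):
                if (role, trig.label, ent.label) in d_r:
                    relations.append(
                        RelationAnnotation(
                            id=f"R{len(relations) + 1}",
                            role=role,
                            trigger_id=trig.id,
                            arg_id=ent.id,
                        )
                    )
    return relations


def end_to_end(
    snippet: Snippet,
    ner_pred: Iterable[EntityAnnotation],
    d_e: TriggerDictionary,
    d_r: RelationDictionary,
    schema: LabelSchema,
) -> Snippet:
    """Two-stage composition: supplied entities + dictionary triggers + co-occurrence events.

    ``ner_pred`` may be gold entities (isolated event-extraction setting)
    or the output of any NER system read from a ``.ann`` file (end-to-end
    setting). Annotations are re-identified T1..Tn in offset order.
    """
    entities = [a for a in ner_pred if schema.is_entity(a.label)]
    triggers = predict_triggers(snippet, d_e)
    merged = sorted(entities + triggers, key=lambda a: (a.start, a.end, a.label))
    renamed: list[EntityAnnotation] = []
    for i, ann in enumerate(merged, start=1):
        renamed.append(
            EntityAnnotation(
                id=f"T{i}", label=ann.label, fragments=ann.fragments, surface=ann.surface
            )
        )
    ent_renamed = [a for a in renamed if schema.is_entity(a.label)]
    trig_renamed = [a for a in renamed if schema.is_trigger(a.label)]
    relations = predict_events(snippet, ent_renamed, trig_renamed, d_r)
    return Snippet(
        key=snippet.key,
        text=snippet.text,
        annotations=renamed,
        relations=relations,
        group=snippet.group,
    )


# ---------------------------------------------------------------------------
# model (de)serialization


def save_model(
    d_e: TriggerDictionary, d_r: RelationDictionary, path
) -> None:
    data = {
        "trigger_dictionary": {
            "lowercase": d_e.lowercase,
            "counts": {k: dict(v) for k, v in sorted(d_e.counts.items())},
            "label_totals": dict(d_e.label_totals),
        },
        "relation_dictionary": sorted(d_r.triples),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def load_model(path) -> tuple[TriggerDictionary, RelationDictionary]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    td = data["trigger_dictionary"]
    d_e = TriggerDictionary(
        counts={k: Counter(v) for k, v in td["counts"].items()},
        label_totals=Counter(td["label_totals"]),
        lowercase=td["lowercase"],
    )
    d_r = RelationDictionary(triples={tuple(t) for t in data["relation_dictionary"]})
    return d_e, d_r
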