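"""Reading, validating and writing snippet corpora in BRAT standoff format.

A corpus is a directory of paired files: ``X.txt`` holds the plain text of
one patent snippet, ``X.ann`` the annotations. Two BRAT line kinds are
meaningful here:

* **T-lines** — one labeled span per line::

      T3\tSOLVENT 25 33\tmethanol

  Discontinuous spans separate their fragments with ``;`` and join the
  covered text with single spaces.

* **R-lines** — one trigger->entity relation per line::

      R1\tArg1 Arg1:T2 Arg2:T5

  The ``Arg1:`` slot names the trigger-word annotation, ``Arg2:`` the
  entity it relates to; the line's own label is the semantic role (Arg1
  or ArgM).

Other BRAT line kinds (comments ``#``, attributes ``A``/``M``, events
``E``, normalizations ``N``, equivalences ``*``) are skipped with a logged
notice. Offsets are 0-based, half-open, character-counted; newlines are
normalized to ``\n`` before any offset arithmetic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .schema import LabelSchema

logger = logging.getLogger(__name__)

Fragment = tuple[int, int]


class BratError(ValueError):
    """Base class for standoff reading/validation failures."""


class BratParseError(BratError):
    """A line could not be parsed as a known BRAT record."""


class BratValidationError(BratError):
    """Parsed records violate snippet-level invariants."""


@dataclass(frozen=True)
class EntityAnnotation:
    """One labeled span (entity or trigger word).

    ``fragments`` is an ordered tuple of half-open (start, end) character
    intervals; ``surface`` is the covered text, with the fragments of a
    discontinuous span joined by a single space.
    """

    id: str
    label: str
    fragments: tuple[Fragment, ...]
    surface: str

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def overlaps(self, other: "EntityAnnotation") -> bool:
        """True if any fragment pair shares at least one character."""
        return any(
            s1 < e2 and s2 < e1
            for (s1, e1) in self.fragments
            for (s2, e2) in other.fragments
        )


@dataclass(frozen=True)
class RelationAnnotation:
    """One semantic-role link from a trigger word to an entity."""

    id: str
    role: str
    trigger_id: str
    arg_id: str


@dataclass
class Snippet:
    """A snippet text plus its annotation set.

    ``group`` optionally records the source document (patent) the snippet
    was excerpted from, for grouped train/test analyses.
    """

    key: str
    text: str
    annotations: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    group: str | None = None

    def annotation_by_id(self, ann_id: str) -> EntityAnnotation:
        for ann in self.annotations:
            if ann.id == ann_id:
                return ann
        raise KeyError(ann_id)

    def entities(self, schema: LabelSchema) -> list[EntityAnnotation]:
        return [a for a in self.annotations if schema.is_entity(a.label)]

    def triggers(self, schema: LabelSchema) -> list[EntityAnnotation]:
        return [a for a in self.annotations if schema.is_trigger(a.label)]


@dataclass
class Corpus:
    """A keyed collection of snippets with an optional split tag."""

    snippets: dict[str, Snippet] = field(default_factory=dict)
    split: str = "none"

    def __len__(self) -> int:
        return len(self.snippets)

    def __iter__(self) -> Iterator[Snippet]:
        return iter(self.snippets.values())

    def keys(self) -> list[str]:
        return list(self.snippets)

    def add(self, snippet: Snippet) -> None:
        if snippet.key in self.snippets:
            raise BratValidationError(f"duplicate snippet key {snippet.key!r}")
        self.snippets[snippet.key] = snippet

    def groups(self) -> set[str]:
        return {s.group for s in self if s.group is not None}

    def subset(self, keys: Iterable[str], split: str | None = None) -> "Corpus":
        return Corpus(
            snippets={k: self.snippets[k] for k in keys},
            split=self.split if split is None else split,
        )


# ---------------------------------------------------------------------------
# parsing


def _normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _parse_fragments(span_field: str, lineno: int) -> tuple[Fragment, ...]:
    fragments: list[Fragment] = []
    for part in span_field.split(";"):
        bits = part.split()
        if len(bits) != 2:
            raise BratParseError(
                f"line {lineno}: malformed span field {span_field!r}"
            )
        try:
            start, end = int(bits[0]), int(bits[1])
        except ValueError as exc:
            raise BratParseError(
                f"line {lineno}: non-integer offset in {span_field!r}"
            ) from exc
        fragments.append((start, end))
    return tuple(fragments)


def expected_surface(text: str, fragments: tuple[Fragment, ...]) -> str:
    """The text a fragment list covers; discontinuous pieces joined by a space."""
    return " ".join(text[s:e] for s, e in fragments)


def parse_snippet(
    text_content: str,
    ann_content: str,
    schema: LabelSchema,
    key: str = "snippet",
    group: str | None = None,
) -> Snippet:
    """Parse one (.txt, .ann) pair into a validated :class:`Snippet`.

    T-lines become :class:`EntityAnnotation`, R-lines become
    :class:`RelationAnnotation`; other BRAT line kinds are ignored with a
    logged notice. Raises :class:`BratParseError` for malformed lines and
    :class:`BratValidationError` for offset/surface/label/endpoint errors.
    """
    text = _normalize_newlines(text_content)
    annotations: list[EntityAnnotation] = []
    relations: list[RelationAnnotation] = []

    for lineno, raw in enumerate(_normalize_newlines(ann_content).split("\n"), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise BratParseError(
                    f"line {lineno}: T-line needs 3 tab-separated fields, got {len(fields)}"
                )
            header = fields[1]
            surface = "\t".join(fields[2:])
            label, _, span_field = header.partition(" ")
            if not span_field:
                raise BratParseError(f"line {lineno}: T-line header lacks offsets")
            fragments = _parse_fragments(span_field, lineno)
            annotations.append(
                EntityAnnotation(id=tag, label=label, fragments=fragments, surface=surface)
            )
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise BratParseError(f"line {lineno}: R-line needs 2 fields")
            bits = fields[1].split()
            if len(bits) != 3:
                raise BratParseError(
                    f"line {lineno}: R-line body must be 'ROLE Arg1:Tx Arg2:Ty'"
                )
            role = bits[0]
            slots: dict[str, str] = {}
            for bit in bits[1:]:
                slot, _, ref = bit.partition(":")
                if slot not in ("Arg1", "Arg2") or not ref:
                    raise BratParseError(
                        f"line {lineno}: malformed relation argument {bit!r}"
                    )
                slots[slot] = ref
            if set(slots) != {"Arg1", "Arg2"}:
                raise BratParseError(
                    f"line {lineno}: relation needs both Arg1: and Arg2: slots"
                )
            relations.append(
                RelationAnnotation(
                    id=tag, role=role, trigger_id=slots["Arg1"], arg_id=slots["Arg2"]
                )
            )
        elif tag[0] in "#AEMN*":
            logger.info("ignoring BRAT line kind %r at line %d", tag[0], lineno)
        else:
            raise BratParseError(f"line {lineno}: unrecognized line {line!r}")

    snippet = Snippet(
        key=key, text=text, annotations=annotations, relations=relations, group=group
    )
    validate_snippet(snippet, schema)
    return snippet


def validate_snippet(snippet: Snippet, schema: LabelSchema) -> None:
    """Check every invariant; raise :class:`BratValidationError` on the first failure."""
    text = snippet.text
    seen_ids: set[str] = set()
    for ann in snippet.annotations:
        if ann.id in seen_ids:
            raise BratValidationError(
                f"{snippet.key}: duplicate annotation id {ann.id!r}"
            )
        seen_ids.add(ann.id)
        if ann.label not in schema.span_labels:
            raise BratValidationError(
                f"{snippet.key}/{ann.id}: unknown label {ann.label!r}; "
                f"allowed: {sorted(schema.span_labels)}"
            )
        if not ann.fragments:
            raise BratValidationError(f"{snippet.key}/{ann.id}: empty fragment list")
        prev_end = -1
        for start, end in ann.fragments:
            if not (0 <= start < end <= len(text)):
                raise BratValidationError(
                    f"{snippet.key}/{ann.id}: span [{start}, {end}) outside text "
                    f"of length {len(text)}"
                )
            if start < prev_end:
                raise BratValidationError(
                    f"{snippet.key}/{ann.id}: fragments overlap or are unsorted"
                )
            prev_end = end
        expected = expected_surface(text, ann.fragments)
        # BRAT writes newlines inside spans as spaces in the surface column
        if ann.surface.replace("\n", " ") != expected.replace("\n", " "):
            raise BratValidationError(
                f"{snippet.key}/{ann.id}: surface {ann.surface!r} does not match "
                f"text {expected!r} at {ann.fragments}"
            )
    by_id = {a.id: a for a in snippet.annotations}
    for rel in snippet.relations:
        if rel.id in seen_ids:
            raise BratValidationError(f"{snippet.key}: duplicate id {rel.id!r}")
        seen_ids.add(rel.id)
        if rel.role not in schema.relation_labels:
            raise BratValidationError(
                f"{snippet.key}/{rel.id}: unknown role {rel.role!r}; "
                f"allowed: {sorted(schema.relation_labels)}"
            )
        for endpoint in (rel.trigger_id, rel.arg_id):
            if endpoint not in by_id:
                raise BratValidationError(
                    f"{snippet.key}/{rel.id}: dangling endpoint {endpoint!r}"
                )
        if not schema.is_trigger(by_id[rel.trigger_id].label):
            raise BratValidationError(
                f"{snippet.key}/{rel.id}: trigger endpoint {rel.trigger_id} carries "
                f"non-trigger label {by_id[rel.trigger_id].label!r}"
            )
        if not schema.is_entity(by_id[rel.arg_id].label):
            raise BratValidationError(
                f"{snippet.key}/{rel.id}: argument endpoint {rel.arg_id} carries "
                f"non-entity label {by_id[rel.arg_id].label!r}"
            )


def validate_corpus(corpus: Corpus, schema: LabelSchema) -> None:
    for snippet in corpus:
        validate_snippet(snippet, schema)


# ---------------------------------------------------------------------------
# writing


def write_snippet(snippet: Snippet) -> tuple[str, str]:
    """Serialize a snippet back to (text_content, ann_content).

    Annotations are emitted sorted by start offset then id, relations by id,
    so output is deterministic and ``parse(write(s)) == s`` up to ordering.
    """
    lines: list[str] = []
    for ann in sorted(snippet.annotations, key=lambda a: (a.start, a.end, a.id)):
        span_field = ";".join(f"{s} {e}" for s, e in ann.fragments)
        surface = ann.surface.replace("\n", " ")
        lines.append(f"{ann.id}\t{ann.label} {span_field}\t{surface}")
    for rel in sorted(snippet.relations, key=lambda r: r.id):
        lines.append(f"{rel.id}\t{rel.role} Arg1:{rel.trigger_id} Arg2:{rel.arg_id}")
    ann_content = "\n".join(lines) + ("\n" if lines else "")
    return snippet.text, ann_content


# ---------------------------------------------------------------------------
# corpus directories


def read_corpus(
    directory: str | Path,
    schema: LabelSchema,
    split: str = "none",
    groups: dict[str, str] | None = None,
) -> Corpus:
    """Read a directory of ``X.txt``/``X.ann`` pairs into a :class:`Corpus`.

    A ``.txt`` without a matching ``.ann`` yields a snippet with zero
    annotations (prediction inputs for the NER task are bare text).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {directory}")
    corpus = Corpus(split=split)
    txt_files = sorted(directory.glob("*.txt"))
    if not txt_files:
        raise BratValidationError(f"no .txt files in {directory}")
    for txt_path in txt_files:
        key = txt_path.stem
        ann_path = txt_path.with_suffix(".ann")
        text_content = txt_path.read_text(encoding="utf-8")
        ann_content = (
            ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        )
        snippet = parse_snippet(
            text_content,
            ann_content,
            schema,
            key=key,
            group=(groups or {}).get(key),
        )
        corpus.add(snippet)
    return corpus


def write_corpus(corpus: Corpus, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for snippet in corpus:
        text_content, ann_content = write_snippet(snippet)
        (directory / f"{snippet.key}.txt").write_text(text_content, encoding="utf-8")
        (directory / f"{snippet.key}.ann").write_text(ann_content, encoding="utf-8")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (snippet key, group id)."""
    groups: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        bits = line.split("\t")
        if len(bits) != 2:
            raise BratParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        groups[bits[0]] = bits[1]
    return groups


def write_group_map(corpus: Corpus, path: str | Path) -> None:
    lines = [
        f"{s.key}\t{s.group}" for s in corpus if s.group is not None
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# statistics


def label_distribution(corpus: Corpus, schema: LabelSchema) -> dict[str, float]:
    """Proportion of span annotations per label (10 entity + 2 trigger), summing to 1."""
    counts: Counter[str] = Counter()
    for snippet in corpus:
        for ann in snippet.annotations:
            counts[ann.label] += 1
    total = sum(counts.values())
    if total == 0:
        raise BratValidationError("cannot compute label distribution of empty corpus")
    return {lab: counts.get(lab, 0) / total for lab in schema.span_labels}
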