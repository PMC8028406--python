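"""Scoring predicted annotations and events against a gold standard.

Entity matching follows the shared-task convention: a predicted and a gold
entity match iff their labels match and their spans match. Spans can be
compared under **exact** matching (identical start and end offsets — for
discontinuous spans, identical fragment lists) or **relaxed** matching (any
character overlap). Labels can be compared at the **fine** level (the ten
entity labels plus two trigger labels) or the **high** level, where each
fine entity label is collapsed to its category (e.g. both
STARTING_MATERIAL and REAGENT_CATALYST specialize COMPOUND). Relaxed
matching relaxes spans only — label agreement is always required.

Events are (role, trigger, argument) instances expanded from relation
annotations; two events match iff their roles are equal and both the
trigger and the argument match as entities under the active criterion.

Precision, recall and F1 are micro-averaged: TP/FP/FN are pooled over all
snippets before the ratios are taken.

Pairing is one-to-one and maximum-cardinality: candidate pairs are seeded
greedily in (descending overlap length, ascending gold start, ascending
predicted start) order and then completed by augmenting paths, so the TP
count always equals exhaustive maximum bipartite matching (a plain greedy
pass can under-count on chains of partially overlapping relaxed matches).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .brat import Corpus, EntityAnnotation, Snippet
from .schema import NEG_LABEL, LabelSchema

logger = logging.getLogger(__name__)


class SpanMode(str, enum.Enum):
    EXACT = "exact"
    RELAXED = "relaxed"


class LabelLevel(str, enum.Enum):
    FINE = "fine"
    HIGHLEVEL = "high"


@dataclass(frozen=True)
class MatchCriterion:
    """One evaluation configuration: span mode x label level."""

    span_mode: SpanMode = SpanMode.EXACT
    label_level: LabelLevel = LabelLevel.FINE


@dataclass
class LabelTally:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class PRFReport:
    """Micro-averaged precision/recall/F1 with a per-label breakdown.

    Degenerate conventions: P=0 when there are no predictions, R=0 when
    there is no gold; if both gold and predictions are empty the score is
    vacuously perfect (P=R=F=1), so self-scoring any corpus gives F=1.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_label: dict[str, LabelTally] = field(default_factory=dict)

    @property
    def _vacuous(self) -> bool:
        return self.tp == self.fp == self.fn == 0

    @property
    def precision(self) -> float:
        if self._vacuous:
            return 1.0
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        if self._vacuous:
            return 1.0
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        if self._vacuous:
            return 1.0
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def _tally(self, label: str) -> LabelTally:
        return self.per_label.setdefault(label, LabelTally())

    def merge(self, other: "PRFReport") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        for label, tally in other.per_label.items():
            mine = self._tally(label)
            mine.tp += tally.tp
            mine.fp += tally.fp
            mine.fn += tally.fn

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label in sorted(self.per_label):
            t = self.per_label[label]
            rows.append(
                {
                    "label": label,
                    "tp": t.tp,
                    "fp": t.fp,
                    "fn": t.fn,
                    "precision": t.precision,
                    "recall": t.recall,
                    "f1": t.f1,
                }
            )
        rows.append(
            {
                "label": "OVERALL",
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# span / label matching primitives


def _fragment_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_length(a: EntityAnnotation, b: EntityAnnotation) -> int:
    """Total number of shared characters across all fragment pairs."""
    return sum(
        _fragment_overlap(fa, fb) for fa in a.fragments for fb in b.fragments
    )


def spans_match(a: EntityAnnotation, b: EntityAnnotation, mode: SpanMode) -> bool:
    """Exact: identical fragment lists. Relaxed: >=1 character of overlap.

    Half-open adjacency ([10,20) vs [20,25)) is not overlap.
    """
    if mode is SpanMode.EXACT:
        return a.fragments == b.fragments
    return overlap_length(a, b) > 0


def map_label(label: str, level: LabelLevel, schema: LabelSchema) -> str:
    """Fine level: identity. High level: the entity label's category; triggers map to themselves."""
    schema.validate_span_label(label)
    if level is LabelLevel.FINE or schema.is_trigger(label):
        return label
    return schema.highlevel_map[label]


def labels_match(
    a: str, b: str, level: LabelLevel, schema: LabelSchema
) -> bool:
    return map_label(a, level, schema) == map_label(b, level, schema)


# ---------------------------------------------------------------------------
# one-to-one pairing


def _max_pairing(
    candidates: list[tuple], n_gold: int, n_pred: int
) -> list[tuple[int, int]]:
    """Maximum-cardinality one-to-one pairing from (sort key..., gi, pi) tuples.

    A greedy pass in sort order seeds the matching (so ties resolve toward
    larger overlaps and earlier offsets), then unmatched gold items search
    for augmenting paths, guaranteeing the pairing size equals the maximum
    bipartite matching.
    """
    ordered = sorted(candidates)
    match_gold = [-1] * n_gold  # gi -> pi
    match_pred = [-1] * n_pred  # pi -> gi
    for *_, gi, pi in ordered:
        if match_gold[gi] == -1 and match_pred[pi] == -1:
            match_gold[gi] = pi
            match_pred[pi] = gi
    adjacency: list[list[int]] = [[] for _ in range(n_gold)]
    for *_, gi, pi in ordered:
        adjacency[gi].append(pi)

    def augment(gi: int, visited: set[int]) -> bool:
        for pi in adjacency[gi]:
            if pi in visited:
                continue
            visited.add(pi)
            if match_pred[pi] == -1 or augment(match_pred[pi], visited):
                match_pred[pi] = gi
                match_gold[gi] = pi
                return True
        return False

    for gi in range(n_gold):
        if match_gold[gi] == -1:
            augment(gi, set())
    return [(gi, pi) for gi, pi in enumerate(match_gold) if pi != -1]


def match_entities(
    gold: list[EntityAnnotation],
    pred: list[EntityAnnotation],
    crit: MatchCriterion,
    schema: LabelSchema,
) -> tuple[list[tuple[EntityAnnotation, EntityAnnotation]], PRFReport]:
    """One-to-one pairing of predicted against gold annotations plus its tallies.

    Candidate pairs must agree on (mapped) label and satisfy the span
    criterion; the pairing is maximum-cardinality, with ties resolved
    toward larger overlaps, then earlier gold and predicted start offsets.
    """
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(pred):
            if not labels_match(g.label, p.label, crit.label_level, schema):
                continue
            if not spans_match(g, p, crit.span_mode):
                continue
            candidates.append((-overlap_length(g, p), g.start, p.start, gi, pi))
    pairs = _max_pairing(candidates, len(gold), len(pred))

    report = PRFReport()
    matched_gold = {gi for gi, _ in pairs}
    matched_pred = {pi for _, pi in pairs}
    for gi, _ in pairs:
        label = map_label(gold[gi].label, crit.label_level, schema)
        report.tp += 1
        report._tally(label).tp += 1
    for gi, g in enumerate(gold):
        if gi not in matched_gold:
            report.fn += 1
            report._tally(map_label(g.label, crit.label_level, schema)).fn += 1
    for pi, p in enumerate(pred):
        if pi not in matched_pred:
            report.fp += 1
            report._tally(map_label(p.label, crit.label_level, schema)).fp += 1
    return [(gold[gi], pred[pi]) for gi, pi in pairs], report


def _check_alignment(gold: Corpus, pred: Corpus) -> None:
    extra = set(pred.snippets) - set(gold.snippets)
    if extra:
        raise KeyError(
            f"prediction snippets absent from gold corpus: {sorted(extra)[:5]}"
        )


def score_ner(
    gold: Corpus,
    pred: Corpus,
    crit: MatchCriterion,
    schema: LabelSchema,
) -> PRFReport:
    """Micro-averaged span-annotation scoring over a whole corpus.

    Prediction snippet keys must be a subset of gold keys; a gold snippet
    with no prediction file counts all its annotations as false negatives.
    """
    _check_alignment(gold, pred)
    report = PRFReport()
    for key, gold_snip in gold.snippets.items():
        pred_snip = pred.snippets.get(key)
        pred_anns = pred_snip.annotations if pred_snip is not None else []
        _, snip_report = match_entities(gold_snip.annotations, pred_anns, crit, schema)
        report.merge(snip_report)
    return report


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class EventInstance:
    """One relation instance expanded to concrete endpoints."""

    role: str
    trigger_label: str
    trigger_fragments: tuple[tuple[int, int], ...]
    argument_label: str
    argument_fragments: tuple[tuple[int, int], ...]

    @classmethod
    def from_snippet(cls, snippet: Snippet) -> list["EventInstance"]:
        instances = []
        for rel in snippet.relations:
            trig = snippet.annotation_by_id(rel.trigger_id)
            arg = snippet.annotation_by_id(rel.arg_id)
            instances.append(
                cls(
                    role=rel.role,
                    trigger_label=trig.label,
                    trigger_fragments=trig.fragments,
                    argument_label=arg.label,
                    argument_fragments=arg.fragments,
                )
            )
        deduped = list(dict.fromkeys(instances))
        if len(deduped) < len(instances):
            logger.warning(
                "%s: %d duplicate relation instance(s) removed before scoring",
                snippet.key,
                len(instances) - len(deduped),
            )
        return deduped

    def _as_annotations(self) -> tuple[EntityAnnotation, EntityAnnotation]:
        return (
            EntityAnnotation("T", self.trigger_label, self.trigger_fragments, ""),
            EntityAnnotation("A", self.argument_label, self.argument_fragments, ""),
        )


def _events_match(
    g: EventInstance, p: EventInstance, crit: MatchCriterion, schema: LabelSchema
) -> bool:
    if g.role != p.role:
        return False
    gt, ga = g._as_annotations()
    pt, pa = p._as_annotations()
    return (
        labels_match(gt.label, pt.label, crit.label_level, schema)
        and spans_match(gt, pt, crit.span_mode)
        and labels_match(ga.label, pa.label, crit.label_level, schema)
        and spans_match(ga, pa, crit.span_mode)
    )


def match_events(
    gold_events: list[EventInstance],
    pred_events: list[EventInstance],
    crit: MatchCriterion,
    schema: LabelSchema,
) -> tuple[list[tuple[int, int]], PRFReport]:
    """One-to-one maximum pairing of event instances, micro tallies per role+trigger label."""
    candidates = []
    for gi, g in enumerate(gold_events):
        for pi, p in enumerate(pred_events):
            if not _events_match(g, p, crit, schema):
                continue
            gt, ga = g._as_annotations()
            pt, pa = p._as_annotations()
            total_overlap = overlap_length(gt, pt) + overlap_length(ga, pa)
            candidates.append(
                (-total_overlap, gt.start, ga.start, pt.start, pa.start, gi, pi)
            )
    pairs = _max_pairing(candidates, len(gold_events), len(pred_events))

    report = PRFReport()
    matched_gold = {gi for gi, _ in pairs}
    matched_pred = {pi for _, pi in pairs}

    def event_key(e: EventInstance) -> str:
        return f"{e.role}:{e.trigger_label}"

    for gi, _ in pairs:
        report.tp += 1
        report._tally(event_key(gold_events[gi])).tp += 1
    for gi, g in enumerate(gold_events):
        if gi not in matched_gold:
            report.fn += 1
            report._tally(event_key(g)).fn += 1
    for pi, p in enumerate(pred_events):
        if pi not in matched_pred:
            report.fp += 1
            report._tally(event_key(p)).fp += 1
    return pairs, report


def score_events(
    gold: Corpus,
    pred: Corpus,
    crit: MatchCriterion,
    schema: LabelSchema,
) -> PRFReport:
    """Micro-averaged event scoring: roles must be equal, trigger and argument must match."""
    _check_alignment(gold, pred)
    report = PRFReport()
    for key, gold_snip in gold.snippets.items():
        pred_snip = pred.snippets.get(key)
        gold_events = EventInstance.from_snippet(gold_snip)
        pred_events = (
            EventInstance.from_snippet(pred_snip) if pred_snip is not None else []
        )
        _, snip_report = match_events(gold_events, pred_events, crit, schema)
        report.merge(snip_report)
    return report


# ---------------------------------------------------------------------------
# confusion matrix


@dataclass
class ConfusionMatrix:
    """Gold-label x predicted-label counts under exact span matching.

    NEG rows/columns collect spans annotated on one side only: a gold
    annotation with no exact-span predicted counterpart counts in
    (gold label, NEG); a predicted annotation with no exact-span gold
    counterpart counts in (NEG, predicted label). The NEG/NEG cell is 0 by
    construction.
    """

    labels: tuple[str, ...]
    counts: Counter[tuple[str, str]] = field(default_factory=Counter)

    def to_dataframe(self) -> pd.DataFrame:
        axes = list(self.labels) + [NEG_LABEL]
        return pd.DataFrame(
            [[self.counts.get((g, p), 0) for p in axes] for g in axes],
            index=axes,
            columns=axes,
        )

    def off_diagonal(self) -> int:
        """Label-confusion count: both sides annotated, labels differ (NEG excluded)."""
        return sum(
            c
            for (g, p), c in self.counts.items()
            if g != p and g != NEG_LABEL and p != NEG_LABEL
        )


def confusion_matrix(gold: Corpus, pred: Corpus, schema: LabelSchema) -> ConfusionMatrix:
    """Exact-span confusion matrix over all span annotations."""
    _check_alignment(gold, pred)
    cm = ConfusionMatrix(labels=schema.span_labels)
    for key, gold_snip in gold.snippets.items():
        pred_snip = pred.snippets.get(key)
        pred_anns = list(pred_snip.annotations) if pred_snip is not None else []
        used = [False] * len(pred_anns)
        by_span: dict[tuple, list[int]] = {}
        for pi, p in enumerate(pred_anns):
            by_span.setdefault(p.fragments, []).append(pi)
        for g in gold_snip.annotations:
            matched_pi = None
            # prefer a same-span prediction with the same label
            for pi in by_span.get(g.fragments, []):
                if not used[pi] and pred_anns[pi].label == g.label:
                    matched_pi = pi
                    break
            if matched_pi is None:
                for pi in by_span.get(g.fragments, []):
                    if not used[pi]:
                        matched_pi = pi
                        break
            if matched_pi is None:
                cm.counts[(g.label, NEG_LABEL)] += 1
            else:
                used[matched_pi] = True
                cm.counts[(g.label, pred_anns[matched_pi].label)] += 1
        for pi, p in enumerate(pred_anns):
            if not used[pi]:
                cm.counts[(NEG_LABEL, p.label)] += 1
    return cm


# ---------------------------------------------------------------------------
# inter-annotator agreement


def pairwise_f1(
    ann_a: Corpus, ann_b: Corpus, crit: MatchCriterion, schema: LabelSchema
) -> float:
    """Pairwise F1 between two annotators (symmetric: swapping A/B swaps FP/FN only)."""
    if set(ann_a.snippets) != set(ann_b.snippets):
        raise KeyError("annotator corpora must cover the same snippet keys")
    return score_ner(ann_a, ann_b, crit, schema).f1


NONE_CATEGORY = "NONE"


@dataclass
class KappaReport:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    n_units: int


def cohens_kappa(ann_a: Corpus, ann_b: Corpus, schema: LabelSchema) -> KappaReport:
    """Cohen's kappa over the union of exact spans annotated by either annotator.

    Each unit is an exact span marked by at least one annotator; an
    annotator assigns it the label of its annotation on that span, or NONE
    if it left the span unannotated. Chance agreement uses each annotator's
    marginal label proportions.
    """
    if set(ann_a.snippets) != set(ann_b.snippets):
        raise KeyError("annotator corpora must cover the same snippet keys")

    assignments: list[tuple[str, str]] = []
    for key in ann_a.snippets:
        a_by_span: dict[tuple, str] = {}
        for ann in ann_a.snippets[key].annotations:
            if ann.fragments in a_by_span:
                logger.warning("%s: annotator A has duplicate span %s", key, ann.fragments)
            a_by_span.setdefault(ann.fragments, ann.label)
        b_by_span: dict[tuple, str] = {}
        for ann in ann_b.snippets[key].annotations:
            if ann.fragments in b_by_span:
                logger.warning("%s: annotator B has duplicate span %s", key, ann.fragments)
            b_by_span.setdefault(ann.fragments, ann.label)
        for span in sorted(set(a_by_span) | set(b_by_span)):
            assignments.append(
                (
                    a_by_span.get(span, NONE_CATEGORY),
                    b_by_span.get(span, NONE_CATEGORY),
                )
            )
    n = len(assignments)
    if n == 0:
        raise ValueError("no annotated units: kappa is undefined")
    p_o = sum(a == b for a, b in assignments) / n
    marg_a = Counter(a for a, _ in assignments)
    marg_b = Counter(b for _, b in assignments)
    categories = set(marg_a) | set(marg_b)
    p_e = sum((marg_a.get(c, 0) / n) * (marg_b.get(c, 0) / n) for c in categories)
    if p_e >= 1.0:
        if p_o == 1.0:
            kappa = 1.0
        else:
            raise ValueError("expected agreement is 1 but observed is not; kappa undefined")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return KappaReport(
        observed_agreement=p_o, expected_agreement=p_e, kappa=kappa, n_units=n
    )
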