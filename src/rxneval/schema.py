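"""Label schema for chemical-reaction snippet corpora.

A snippet is annotated with three kinds of labels:

* ten **entity** labels, grouped into four categories — chemical compounds
  (STARTING_MATERIAL, REAGENT_CATALYST, REACTION_PRODUCT, SOLVENT,
  OTHER_COMPOUND), reaction conditions (TIME, TEMPERATURE), yields
  (YIELD_PERCENT, YIELD_OTHER), and example labels (EXAMPLE_LABEL);
* two **trigger-word** labels for event steps — REACTION_STEP (converts
  starting materials into a product) and WORKUP (isolates/purifies it);
* two **relation** roles linking a trigger word to an entity — Arg1 for a
  causally affected chemical compound, ArgM for an adjunct (time,
  temperature, or yield).

The high-level map collapses each fine entity label into its category so
scorers can run a type-relaxed evaluation (e.g. STARTING_MATERIAL and
REAGENT_CATALYST both specialize COMPOUND).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

COMPOUND_LABELS = (
    "STARTING_MATERIAL",
    "REAGENT_CATALYST",
    "REACTION_PRODUCT",
    "SOLVENT",
    "OTHER_COMPOUND",
)
CONDITION_LABELS = ("TIME", "TEMPERATURE")
YIELD_LABELS = ("YIELD_PERCENT", "YIELD_OTHER")
EXAMPLE_LABELS = ("EXAMPLE_LABEL",)

ENTITY_LABELS = COMPOUND_LABELS + CONDITION_LABELS + YIELD_LABELS + EXAMPLE_LABELS
TRIGGER_LABELS = ("REACTION_STEP", "WORKUP")
RELATION_LABELS = ("Arg1", "ArgM")

#: category name used for unannotated ("none-entity") occurrences in entropy profiles
O_LABEL = "O"
#: pseudo-label used in confusion matrices for spans with no counterpart
NEG_LABEL = "NEG"

DEFAULT_HIGHLEVEL_MAP: dict[str, str] = {
    **{lab: "COMPOUND" for lab in COMPOUND_LABELS},
    **{lab: "REACTION_CONDITION" for lab in CONDITION_LABELS},
    **{lab: "YIELD" for lab in YIELD_LABELS},
    **{lab: "EXAMPLE_LABEL" for lab in EXAMPLE_LABELS},
}


class SchemaError(ValueError):
    """Raised when a label schema violates its invariants."""


@dataclass(frozen=True)
class LabelSchema:
    """The label inventory plus the fine-label -> category map.

    The default instance carries the ten entity labels, the two trigger
    labels, the two relation roles, and the four-category high-level map.
    Alternative schemas (e.g. renamed categories) can be loaded from YAML.
    """

    entity_labels: tuple[str, ...] = ENTITY_LABELS
    trigger_labels: tuple[str, ...] = TRIGGER_LABELS
    relation_labels: tuple[str, ...] = RELATION_LABELS
    highlevel_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HIGHLEVEL_MAP)
    )

    def __post_init__(self) -> None:
        missing = set(self.entity_labels) - set(self.highlevel_map)
        if missing:
            raise SchemaError(
                f"highlevel_map must cover every entity label; missing {sorted(missing)}"
            )
        extra = set(self.highlevel_map) - set(self.entity_labels)
        if extra:
            raise SchemaError(
                f"highlevel_map keys must be entity labels; unknown {sorted(extra)}"
            )

    @property
    def span_labels(self) -> tuple[str, ...]:
        """All 12 labels that can appear on a text span (entities + triggers)."""
        return self.entity_labels + self.trigger_labels

    @property
    def highlevel_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.entity_labels:
            cat = self.highlevel_map[lab]
            if cat not in seen:
                seen.append(cat)
        return tuple(seen)

    def is_entity(self, label: str) -> bool:
        return label in self.entity_labels

    def is_trigger(self, label: str) -> bool:
        return label in self.trigger_labels

    def validate_span_label(self, label: str) -> None:
        if label not in self.span_labels:
            raise SchemaError(
                f"unknown span label {label!r}; allowed: {sorted(self.span_labels)}"
            )

    def validate_relation_label(self, label: str) -> None:
        if label not in self.relation_labels:
            raise SchemaError(
                f"unknown relation label {label!r}; allowed: {sorted(self.relation_labels)}"
            )

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "entity_labels": list(self.entity_labels),
                "trigger_labels": list(self.trigger_labels),
                "relation_labels": list(self.relation_labels),
                "highlevel_map": dict(self.highlevel_map),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "LabelSchema":
        data = yaml.safe_load(text)
        try:
            return cls(
                entity_labels=tuple(data["entity_labels"]),
                trigger_labels=tuple(data["trigger_labels"]),
                relation_labels=tuple(data["relation_labels"]),
                highlevel_map=dict(data["highlevel_map"]),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema file: {exc}") from exc

    @classmethod
    def default(cls) -> "LabelSchema":
        return cls()
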