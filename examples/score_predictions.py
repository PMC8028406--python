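"""Score a prediction corpus against gold under all four matching criteria.

Builds a 30-snippet synthetic gold corpus, injects a known mix of errors
(span shifts, label swaps, deletions, insertions), and scores the result.
The printed table shows how relaxed span matching and high-level label
matching each forgive part of the injected damage: relaxed recovers the
span shifts, high-level recovers the within-category label swaps.
"""

from rxneval import (
    GeneratorConfig,
    LabelLevel,
    LabelSchema,
    MatchCriterion,
    PerturbationSpec,
    SpanMode,
    generate,
    perturb,
    score_ner,
)

schema = LabelSchema.default()
gold = generate(GeneratorConfig(seed=42, n_snippets=30))
pred, ledger = perturb(
    gold,
    PerturbationSpec(
        span_shift_rate=0.08, label_swap_rate=0.08, deletion_rate=0.04, insertion_rate=0.05
    ),
    seed=7,
)
print("injected errors:", ledger.to_json_dict())
print()
print(f"{'span':8} {'labels':6} {'P':>7} {'R':>7} {'F1':>7}")
for span in SpanMode:
    for level in LabelLevel:
        rep = score_ner(gold, pred, MatchCriterion(span, level), schema)
        print(
            f"{span.value:8} {level.value:6} {rep.precision:7.4f} {rep.recall:7.4f} {rep.f1:7.4f}"
        )
print()
print(
    "Each row pools TP/FP/FN over all snippets (micro-averaging); F1 rises"
    "\nfrom exact/fine to relaxed/high as the criteria forgive span slips"
    "\nand within-category label confusions."
)
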