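"""Quantify train/test overlap by similarity bins and entity entropy.

Each test snippet gets its maximum bag-of-words cosine to the training set
(bins Q1-Q4); each test entity surface gets the base-10 entropy of its
training label distribution (bins S1-S4, unseen surfaces = 1.0). A pure
memorization predictor — label every span with its training majority label
— is then scored per entropy bin: it is perfect on S1 (entropy 0) and
degrades on ambiguous and unseen surfaces.
"""

from collections import Counter

from rxneval import (
    Corpus,
    EntityAnnotation,
    GeneratorConfig,
    LabelSchema,
    MatchCriterion,
    Snippet,
    build_entropy_profile,
    generate,
    similarity_bins,
    split,
    stratified_score,
)

schema = LabelSchema.default()
corpus = generate(GeneratorConfig(seed=21, n_snippets=80, ambiguity_rate=0.5, overlap_rate=0.3))
result = split(corpus, seed=21)

q = Counter(similarity_bins(result.test, result.train).values())
print("similarity bins:", dict(sorted(q.items())))

profile = build_entropy_profile(result.train, schema)
print(f"entropy profile covers {len(profile)} surface forms")
print(f"example: E('methanol') = {profile.entropy_of('methanol'):.3f}")

pred = Corpus(split="pred")
for key, snip in result.test.snippets.items():
    anns = []
    for a in snip.entities(schema):
        counts = {k: v for k, v in profile.counts_for(a.surface).items() if k != "O"}
        label = max(sorted(counts), key=lambda k: counts[k]) if counts else "OTHER_COMPOUND"
        anns.append(EntityAnnotation(a.id, label, a.fragments, a.surface))
    pred.add(Snippet(key=key, text=snip.text, annotations=anns))

print()
print(f"{'bin':4} {'boundaries':18} {'n':>5} {'F1':>7}")
for s in stratified_score(result.test, pred, profile, MatchCriterion(), schema):
    print(f"{s.bin_id:4} {s.boundaries:18} {s.n_items:5d} {s.report.f1:7.4f}")
print()
print(
    "F1 decreases from S1 to S3/S4: memorization suffices only where the"
    "\ntraining label distribution of a surface form is unambiguous."
)
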