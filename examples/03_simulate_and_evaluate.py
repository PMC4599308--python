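"""Simulate a pair group with planted specificity and evaluate prediction.

Generates one synthetic pair group (25 homodimers vs 14 monomers,
120 columns, 60% of interface columns drawing from disjoint group
alphabets), scores it, predicts interface residues at SH <= 0.2 and
compares against the planted structural annotation.
"""

from seqharmony import default_spec, evaluate_group, score_group, simulate_pair_group
from seqharmony.io import classify_annotations_inplace

spec = default_spec(seed=1)
result = simulate_pair_group(spec)

scores = score_group(result.group)
classify_annotations_inplace(result.annotations)
report = evaluate_group("demo", scores, result.annotations, cutoff=0.2)

print(f"columns scored:       {len(scores)}")
print(f"confusion counts:     TP={report.counts.tp} FP={report.counts.fp} "
      f"TN={report.counts.tn} FN={report.counts.fn}")
print(f"recall:               {report.recall:.3f}")
print(f"precision:            {report.precision:.3f}")
print(f"false positive rate:  {report.fpr:.3f}")
print(f"ROC AUC:              {report.auc:.3f}")
print("mean SH per class:")
for cls in ("interface", "surface", "buried"):
    print(f"  {cls:10s} {report.class_means[cls]['sh']:.3f}")
print()
print(
    "Interface positions carry the lowest mean SH — the planted\n"
    "group-specificity signal — and an AUC well above 0.5 shows that\n"
    "ranking residues by SH separates interface from non-interface."
)
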