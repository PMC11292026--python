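"""Combine the top tools by majority rule and cross-validate the best one.

Panels vote a variant pathogenic when strictly more than half the members
do; fivefold cross-validation learns the threshold on 80% of variants and
scores the held-out 20%, fold by fold.
"""

import genecalib as gc
from genecalib.ensemble import combinations_table

registry = gc.load_default_registry()
variants, scores = gc.generate_dataset(gc.SyntheticConfig(seed=42), registry)
labels = variants["label"].to_numpy()

optimized, mcc = {}, {}
for tool in registry:
    res = gc.optimize_threshold(scores[tool], labels, registry[tool])
    optimized[tool], mcc[tool] = res.best_threshold, res.best_mcc

top3 = sorted(mcc, key=mcc.get, reverse=True)[:3]
print("top-three tools by optimized MCC:", ", ".join(top3))

results = gc.evaluate_combinations(
    scores, labels, registry, optimized, panel_sizes=(2, 3), tools=top3
)
print(combinations_table(results).round(3).to_string(index=False))
print(f"best single tool ({top3[0]}) MCC: {mcc[top3[0]]:.3f}")
# whether a panel beats the best single tool is a measurable comparison,
# not an assumption — on well-calibrated data a single strong tool often wins

cv = gc.cross_validate(scores[top3[0]], labels, registry[top3[0]], k=5, seed=42)
print(cv.table().round(3).to_string(index=False))
print(f"CV mean MCC {cv.mean['mcc']:.2f} +/- {cv.sd['mcc']:.2f} (sample sd over 5 folds)")
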