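"""Rank the 15 measured athletes with improved TOPSIS.

Loads the packaged athlete stroke-angle table (knee joint angle, thigh
and calf link angles, finger-spread angle) and the example criteria
configuration, runs the TOPSIS pipeline and prints per-athlete closeness
scores, then aggregates by stroke.
"""

from collections import defaultdict

from swimdyn import rank_alternatives
from swimdyn.io import fixture_path, read_criteria, read_decision_matrix

criteria = read_criteria(fixture_path("criteria_example.yaml"))
dm = read_decision_matrix(fixture_path("athlete_angles.csv"), criteria)
result = rank_alternatives(dm)

strokes = {}
with open(fixture_path("athlete_angles.csv")) as fh:
    next(fh)
    for line in fh:
        cells = line.strip().split(",")
        strokes[cells[0]] = cells[-1]

print(f"{'athlete':>8} {'D+':>8} {'D-':>8} {'C':>8} {'rank':>5}  stroke")
for i, name in enumerate(result.alternatives):
    print(
        f"{name:>8} {result.separation_best[i]:8.4f} "
        f"{result.separation_worst[i]:8.4f} {result.closeness[i]:8.4f} "
        f"{result.rank[i]:5d}  {strokes[name]}"
    )

by_stroke = defaultdict(list)
for i, name in enumerate(result.alternatives):
    by_stroke[strokes[name]].append(result.closeness[i])
print("\nmean closeness by stroke (higher = nearer the ideal angles under")
print("this criteria configuration; directions/weights are configurable):")
for stroke, scores in sorted(by_stroke.items(), key=lambda kv: -sum(kv[1]) / len(kv[1])):
    print(f"  {stroke:>13}: {sum(scores) / len(scores):.4f}  (n={len(scores)})")
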