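"""Reproduce the breast-cancer treatment-selection case study.

Seven treatment options, four attributes, q = 6, tau = 8.  The pipeline
enters at the published aggregated matrix (the expert-weight stage of the
source study is not reproducible from its printed inputs — see the package
docs) and recomputes the weighted matrix, border approximation area, signed
distances, cumulative values and ranking.
"""

from tlmabac import breast_cancer, run_pipeline
from tlmabac.io import emit_report

case = breast_cancer()
result = run_pipeline(
    None,
    case.config,
    entry_stage="aggregated",
    aggregated=case.aggregated,
    alternative_ids=case.alternative_ids,
    attribute_ids=case.attribute_ids,
)

print("cumulative values S (signed distance sums; larger = better):")
for name, s in zip(result.alternative_ids, result.cumulative):
    print(f"  {name}: {s:+.4f}")
print("ranking:", " > ".join(result.ranking))
print()
print("Markdown report (excerpt):")
print("\n".join(emit_report(result, format="markdown").splitlines()[:8]))
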