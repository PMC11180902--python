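"""How the rung q changes the case-study ranking.

Rerunning the pipeline across rungs shows which conclusions are robust:
the top alternative here is stable from moderate q upward, while small
rungs (which the elicited data violates — the sweep runs in warn mode)
reshuffle the mid-field.
"""

import logging

from tlmabac import breast_cancer, sensitivity_sweep

# each constraint violation at small q is logged individually; quiet them
logging.getLogger("tlmabac").setLevel(logging.ERROR)

case = breast_cancer()
records = sensitivity_sweep(
    case.config,
    [0.5, 1.5, 3, 6, 9, 20],
    entry_stage="aggregated",
    aggregated=case.aggregated,
    alternative_ids=case.alternative_ids,
)
for rec in records:
    S = ", ".join(f"{s:+.4f}" for s in rec["cumulative"])
    print(f"q = {rec['q']:>4}:  top = {rec['top']}   S = [{S}]")
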