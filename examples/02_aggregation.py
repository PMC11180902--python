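"""Aggregate several judgements with weighted averaging / geometric means.

The closed-form operators and the folds of the elementary operational laws
are two routes to the same number; their agreement below illustrates the
representation theorems behind the operators.
"""

from tlmabac import (
    LinguisticScale,
    TLIVqROFN,
    WeightVector,
    score,
    wa,
    wa_fold,
    wg,
)

scale = LinguisticScale(8)
q = 6
judgements = [
    TLIVqROFN.from_indices(2, 3, 4, 5, scale),
    TLIVqROFN.from_indices(5, 6, 1, 2, scale),
    TLIVqROFN.from_indices(3, 4, 3, 4, scale),
]
w = WeightVector((0.5, 0.3, 0.2))

avg = wa(judgements, w, q)
geo = wg(judgements, w, q)
print("weighted average :", avg, f"  K = {score(avg, q):.4f}")
print("weighted geometric:", geo, f"  K = {score(geo, q):.4f}")
# the geometric mean penalizes poor judgements harder, so K(wg) <= K(wa)

fold = wa_fold(judgements, w, q)
dev = max(abs(x - y) for x, y in zip(avg.xi(), fold.xi()))
print(f"closed form vs operational fold, max deviation: {dev:.2e}")

# a weight vector that does not sum to 1 is used verbatim by default
# (a warning is logged); 'renormalize' rescales it instead
uneven = WeightVector((0.2192, 0.2134, 0.1930), policy="renormalize")
print("renormalized weights:", [round(x, 4) for x in uneven.resolve()])
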