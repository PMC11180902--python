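"""Build linguistic fuzzy judgements and compare them.

An assessment on a 9-term scale (tau = 8) is an interval membership and an
interval non-membership, each endpoint a linguistic 2-tuple.  The score
function K summarizes a judgement on [0, 1] (0.5 is neutral); accuracy F
measures how much total information the judgement carries and breaks score
ties.
"""

from tlmabac import (
    LinguisticScale,
    TLIVqROFN,
    accuracy,
    compare,
    hamming,
    score,
    validate,
)

scale = LinguisticScale(8)
q = 6

# "membership somewhere between J2 and J3, non-membership between J4 and J5"
R1 = TLIVqROFN.from_indices(2, 3, 4, 5, scale)
# a more favourable judgement
R2 = TLIVqROFN.from_indices(5, 6, 1, 2, scale)

print(f"R1 = {R1}   K = {score(R1, q):.4f}   F = {accuracy(R1, q):.5f}")
print(f"R2 = {R2}   K = {score(R2, q):.4f}   F = {accuracy(R2, q):.5f}")
print("R2 > R1?", compare(R2, R1, q) == 1)
print(f"normalized Hamming distance d(R1, R2) = {hamming(R1, R2, q):.4f}")

# the rung constraint: the same data that is valid at q = 6 can violate
# the constraint at q = 0.5
extreme = TLIVqROFN.from_indices(1, 7, 2, 4, scale)
print("valid at q=6:  ", validate(extreme, 6, mode="warn").ok)
print("valid at q=0.5:", validate(extreme, 0.5, mode="warn").ok)
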