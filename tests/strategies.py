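"""Hypothesis strategies for valid fuzzy numbers (tau = 8)."""

from hypothesis import strategies as st

from tlmabac import LinguisticScale, TLIVqROFN

SCALE8 = LinguisticScale(8)

_unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False, width=32)


@st.composite
def rofn(draw, q: float = 6.0, scale: LinguisticScale = SCALE8) -> TLIVqROFN:
    """A valid number: ordered intervals satisfying b^q + d^q <= 1."""
    b = draw(_unit)
    d_cap = (1.0 - b ** q) ** (1.0 / q) if b < 1.0 else 0.0
    d = draw(_unit) * d_cap
    a = draw(_unit) * b
    c = draw(_unit) * d
    return TLIVqROFN.from_unit(a, b, c, d, scale)
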