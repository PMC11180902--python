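"""High-precision re-evaluation of the closed-form operations.

Independent oracle used by the tests: the same formulas evaluated in
``decimal`` arithmetic at 60 significant digits, structured as elementwise
folds rather than product closed forms so the aggregation checks exercise a
genuinely different code path.
"""

from decimal import Decimal, localcontext
from typing import Sequence

PREC = 60


def _d(x: float) -> Decimal:
    return Decimal(repr(x))


def _dpow(base: Decimal, exponent: Decimal) -> Decimal:
    if exponent == 0:
        return Decimal(1)
    if base == 0:
        return Decimal(0)
    return (exponent * base.ln()).exp()


def unit(R, tau: int | None = None) -> tuple[Decimal, Decimal, Decimal, Decimal]:
    """Exact tau-normalized components of a fuzzy number."""
    tau = tau if tau is not None else R.scale.tau
    return tuple(_d(x) / Decimal(tau) for x in R.xi())  # type: ignore[return-value]


def score(R, q: float) -> Decimal:
    with localcontext() as ctx:
        ctx.prec = PREC
        a, b, c, d = unit(R)
        dq = _d(q)
        return (
            (1 + _dpow(a, dq) - _dpow(c, dq)) + (1 + _dpow(b, dq) - _dpow(d, dq))
        ) / 4


def accuracy(R, q: float) -> Decimal:
    with localcontext() as ctx:
        ctx.prec = PREC
        dq = _d(q)
        return sum(_dpow(x, dq) for x in unit(R)) / 4


def hamming(R1, R2, q: float) -> Decimal:
    with localcontext() as ctx:
        ctx.prec = PREC
        dq = _d(q)
        return (
            sum(abs(_dpow(x1, dq) - _dpow(x2, dq)) for x1, x2 in zip(unit(R1), unit(R2)))
            / 4
        )


def _add_mem(x1: Decimal, x2: Decimal, q: Decimal) -> Decimal:
    p1, p2 = _dpow(x1, q), _dpow(x2, q)
    return _dpow(p1 + p2 - p1 * p2, 1 / q)


def add(u1: Sequence[Decimal], u2: Sequence[Decimal], q: float) -> list[Decimal]:
    """Elementwise sum law on unit-scale 4-vectors."""
    with localcontext() as ctx:
        ctx.prec = PREC
        dq = _d(q)
        a1, b1, c1, d1 = u1
        a2, b2, c2, d2 = u2
        return [_add_mem(a1, a2, dq), _add_mem(b1, b2, dq), c1 * c2, d1 * d2]


def scalar_mul(eps: float, u: Sequence[Decimal], q: float) -> list[Decimal]:
    with localcontext() as ctx:
        ctx.prec = PREC
        dq, de = _d(q), _d(eps)
        a, b, c, d = u
        return [
            _dpow(1 - _dpow(1 - _dpow(a, dq), de), 1 / dq),
            _dpow(1 - _dpow(1 - _dpow(b, dq), de), 1 / dq),
            _dpow(c, de),
            _dpow(d, de),
        ]


def mul(u1: Sequence[Decimal], u2: Sequence[Decimal], q: float) -> list[Decimal]:
    with localcontext() as ctx:
        ctx.prec = PREC
        dq = _d(q)
        a1, b1, c1, d1 = u1
        a2, b2, c2, d2 = u2
        return [a1 * a2, b1 * b2, _add_mem(c1, c2, dq), _add_mem(d1, d2, dq)]


def power(u: Sequence[Decimal], eps: float, q: float) -> list[Decimal]:
    with localcontext() as ctx:
        ctx.prec = PREC
        dq, de = _d(q), _d(eps)
        a, b, c, d = u
        return [
            _dpow(a, de),
            _dpow(b, de),
            _dpow(1 - _dpow(1 - _dpow(c, dq), de), 1 / dq),
            _dpow(1 - _dpow(1 - _dpow(d, dq), de), 1 / dq),
        ]


def wa_fold(elements, weights: Sequence[float], q: float) -> list[Decimal]:
    """Weighted average as a decimal fold of scalar_mul and add."""
    with localcontext() as ctx:
        ctx.prec = PREC
        acc = scalar_mul(weights[0], unit(elements[0]), q)
        for R, w in zip(elements[1:], weights[1:]):
            acc = add(acc, scalar_mul(w, unit(R), q), q)
        return acc


def wg_fold(elements, weights: Sequence[float], q: float) -> list[Decimal]:
    """Weighted geometric mean as a decimal fold of power and mul."""
    with localcontext() as ctx:
        ctx.prec = PREC
        acc = power(unit(elements[0]), weights[0], q)
        for R, w in zip(elements[1:], weights[1:]):
            acc = mul(acc, power(unit(R), w, q), q)
        return acc
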