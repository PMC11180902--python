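"""Interval-valued q-rung orthopair fuzzy numbers on a linguistic 2-tuple scale.

A 2TLIVq-ROFN expresses an expert judgement as an interval membership degree
[r, t] and an interval non-membership degree [u, y], each endpoint a
linguistic 2-tuple on a common term scale J_0..J_tau.  On the unit scale
(endpoints divided by tau) the defining constraint is

    (t/tau)^q + (y/tau)^q <= 1,        q > 0,

i.e. the q-th powers of the upper membership and upper non-membership must
not jointly exceed one.  Larger rungs q admit more extreme judgements;
q = 1 recovers interval-valued intuitionistic and q = 2 interval-valued
Pythagorean behaviour.

All arithmetic here happens on tau-normalized reals; 2-tuple encoding is
applied only when results are materialized, so chained operations do not
accumulate rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from .errors import ConstraintError, DomainError, IncompatibleScaleError
from .linguistic import LinguisticScale, TwoTuple, delta

__all__ = [
    "TLIVqROFN",
    "ValidationReport",
    "validate",
    "score",
    "accuracy",
    "compare",
    "add",
    "mul",
    "scalar_mul",
    "power",
    "complement",
    "hamming",
]

logger = logging.getLogger("tlmabac")

#: tolerance for score/accuracy ties in :func:`compare`
TIE_TOL = 1e-9


def _clamp01(x: float) -> float:
    # guards against tiny negative radicands / >1 probabilities from
    # floating-point underflow in the power laws
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


def _pow(base: float, exponent: float) -> float:
    """0^e = 0 for e > 0, x^0 = 1; otherwise ordinary power on [0, 1]."""
    if exponent == 0.0:
        return 1.0
    if base == 0.0:
        return 0.0
    return base ** exponent


def _one_minus_pow(p: float, w: float) -> float:
    """1 - (1 - p)^w for p in [0, 1], without cancellation for small p.

    The naive form loses relative accuracy when p^... is tiny (routine at
    large rungs q, where components enter as x^q); expm1/log1p keeps full
    relative precision, which the q-th root downstream would otherwise
    amplify.
    """
    if w == 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    return -math.expm1(w * math.log1p(-p))


@dataclass(frozen=True)
class TLIVqROFN:
    """A 2-tuple linguistic interval-valued q-rung orthopair fuzzy number.

    ``r``/``t`` are the lower/upper membership 2-tuples and ``u``/``y`` the
    lower/upper non-membership 2-tuples, all on ``scale``.  Interval
    ordering (r <= t, u <= y) is enforced at construction; the rung-q
    constraint is checked separately by :func:`validate` because it depends
    on q.
    """

    r: TwoTuple
    t: TwoTuple
    u: TwoTuple
    y: TwoTuple
    scale: LinguisticScale

    def __post_init__(self) -> None:
        tau = self.scale.tau
        for name, tt in zip("rtuy", (self.r, self.t, self.u, self.y)):
            if not (0 <= tt.value <= tau):
                raise DomainError(
                    f"component {name} = {tt} outside the scale range [0, {tau}]"
                )
        if self.r.value > self.t.value:
            raise ConstraintError(
                f"membership interval disordered: {self.r} > {self.t}"
            )
        if self.u.value > self.y.value:
            raise ConstraintError(
                f"non-membership interval disordered: {self.u} > {self.y}"
            )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_xi(
        cls, r: float, t: float, u: float, y: float, scale: LinguisticScale
    ) -> "TLIVqROFN":
        """Build from four real values on [0, tau]."""
        return cls(
            delta(r, scale), delta(t, scale), delta(u, scale), delta(y, scale), scale
        )

    @classmethod
    def from_unit(
        cls, a: float, b: float, c: float, d: float, scale: LinguisticScale
    ) -> "TLIVqROFN":
        """Build from four unit-scale values in [0, 1]."""
        tau = scale.tau
        return cls.from_xi(a * tau, b * tau, c * tau, d * tau, scale)

    @classmethod
    def from_indices(
        cls, r: int, t: int, u: int, y: int, scale: LinguisticScale
    ) -> "TLIVqROFN":
        """Build from crisp term indices (zero symbolic translations)."""
        return cls(TwoTuple(r), TwoTuple(t), TwoTuple(u), TwoTuple(y), scale)

    # -- views ---------------------------------------------------------

    def xi(self) -> tuple[float, float, float, float]:
        """The four real values Delta^-1(r), Delta^-1(t), Delta^-1(u), Delta^-1(y)."""
        return (self.r.value, self.t.value, self.u.value, self.y.value)

    def unit(self) -> tuple[float, float, float, float]:
        """The four tau-normalized components (a, b, c, d) in [0, 1]."""
        tau = self.scale.tau
        return tuple(x / tau for x in self.xi())  # type: ignore[return-value]

    def __str__(self) -> str:
        return f"([{self.r}, {self.t}], [{self.u}, {self.y}])"

    # -- thin method wrappers around the module-level operations -------

    def score(self, q: float) -> float:
        return score(self, q)

    def accuracy(self, q: float) -> float:
        return accuracy(self, q)

    def complement(self) -> "TLIVqROFN":
        return complement(self)

    def hamming(self, other: "TLIVqROFN", q: float) -> float:
        return hamming(self, other, q)


def _check_rung(q: float) -> None:
    if not q > 0:
        raise DomainError(f"rung q must be positive, got {q}")


def _check_compatible(R1: TLIVqROFN, R2: TLIVqROFN) -> None:
    if R1.scale.tau != R2.scale.tau:
        raise IncompatibleScaleError(
            f"operands on different scales: tau={R1.scale.tau} vs tau={R2.scale.tau}"
        )


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    messages: tuple[str, ...] = ()


def validate(
    R: TLIVqROFN, q: float, mode: str = "warn", label: str | None = None
) -> ValidationReport:
    """Check the rung-q constraint (t/tau)^q + (y/tau)^q <= 1.

    ``mode``: ``"strict"`` raises :class:`ConstraintError` on violation,
    ``"warn"`` logs a diagnostic and passes, ``"off"`` skips the check.
    Interval ordering is already enforced at construction and is not
    re-checked here.
    """
    _check_rung(q)
    if mode not in ("strict", "warn", "off"):
        raise DomainError(f"unknown validation mode {mode!r}")
    if mode == "off":
        return ValidationReport(True)
    _, b, _, d = R.unit()
    lhs = b ** q + d ** q
    if lhs <= 1.0 + 1e-12:
        return ValidationReport(True)
    where = f" at {label}" if label else ""
    msg = (
        f"rung constraint violated{where}: ({R.t})^q + ({R.y})^q gives "
        f"{lhs:.6g} > 1 on the unit scale (q={q}, tau={R.scale.tau})"
    )
    if mode == "strict":
        raise ConstraintError(msg)
    logger.warning(msg)
    return ValidationReport(False, (msg,))


def score(R: TLIVqROFN, q: float) -> float:
    """Score function K on the unit scale, in [0, 1].

    K = 1/4 [(1 + a^q - c^q) + (1 + b^q - d^q)] with (a, b, c, d) the four
    tau-normalized components.  Use :func:`score_two_tuple` for the
    linguistic form Delta(tau * K).
    """
    _check_rung(q)
    a, b, c, d = R.unit()
    return 0.25 * ((1.0 + a ** q - c ** q) + (1.0 + b ** q - d ** q))


def score_two_tuple(R: TLIVqROFN, q: float) -> TwoTuple:
    """The score expressed linguistically as Delta(tau * K)."""
    return delta(R.scale.tau * score(R, q), R.scale)


def accuracy(R: TLIVqROFN, q: float) -> float:
    """Accuracy function F = 1/4 (a^q + b^q + c^q + d^q) on the unit scale."""
    _check_rung(q)
    a, b, c, d = R.unit()
    return 0.25 * (a ** q + b ** q + c ** q + d ** q)


def accuracy_two_tuple(R: TLIVqROFN, q: float) -> TwoTuple:
    """The accuracy expressed linguistically as Delta(tau * F)."""
    return delta(R.scale.tau * accuracy(R, q), R.scale)


def compare(R1: TLIVqROFN, R2: TLIVqROFN, q: float, tol: float = TIE_TOL) -> int:
    """Total order: by score, then accuracy; returns -1, 0 or 1.

    Scores (and, on a score tie, accuracies) closer than ``tol`` are treated
    as equal.
    """
    _check_compatible(R1, R2)
    k1, k2 = score(R1, q), score(R2, q)
    if abs(k1 - k2) > tol:
        return 1 if k1 > k2 else -1
    f1, f2 = accuracy(R1, q), accuracy(R2, q)
    if abs(f1 - f2) > tol:
        return 1 if f1 > f2 else -1
    return 0


def add(R1: TLIVqROFN, R2: TLIVqROFN, q: float) -> TLIVqROFN:
    """The sum R1 (+) R2.

    Membership endpoints combine by the q-power probabilistic sum
    (x1^q + x2^q - x1^q x2^q)^(1/q); non-membership endpoints multiply.
    """
    _check_rung(q)
    _check_compatible(R1, R2)
    a1, b1, c1, d1 = R1.unit()
    a2, b2, c2, d2 = R2.unit()
    a = _clamp01(a1 ** q + a2 ** q - a1 ** q * a2 ** q) ** (1.0 / q)
    b = _clamp01(b1 ** q + b2 ** q - b1 ** q * b2 ** q) ** (1.0 / q)
    return TLIVqROFN.from_unit(a, b, c1 * c2, d1 * d2, R1.scale)


def mul(R1: TLIVqROFN, R2: TLIVqROFN, q: float) -> TLIVqROFN:
    """The product R1 (x) R2: dual of :func:`add`."""
    _check_rung(q)
    _check_compatible(R1, R2)
    a1, b1, c1, d1 = R1.unit()
    a2, b2, c2, d2 = R2.unit()
    c = _clamp01(c1 ** q + c2 ** q - c1 ** q * c2 ** q) ** (1.0 / q)
    d = _clamp01(d1 ** q + d2 ** q - d1 ** q * d2 ** q) ** (1.0 / q)
    return TLIVqROFN.from_unit(a1 * a2, b1 * b2, c, d, R1.scale)


def scalar_mul(eps: float, R: TLIVqROFN, q: float) -> TLIVqROFN:
    """Scalar multiple eps * R for eps >= 0.

    Membership endpoints map to (1 - (1 - x^q)^eps)^(1/q), non-membership
    endpoints to x^eps.
    """
    _check_rung(q)
    if eps < 0:
        raise DomainError(f"scalar must be non-negative, got {eps}")
    a, b, c, d = R.unit()
    na = _one_minus_pow(a ** q, eps) ** (1.0 / q)
    nb = _one_minus_pow(b ** q, eps) ** (1.0 / q)
    return TLIVqROFN.from_unit(na, nb, _pow(c, eps), _pow(d, eps), R.scale)


def power(R: TLIVqROFN, eps: float, q: float) -> TLIVqROFN:
    """The power R^eps for eps >= 0: dual of :func:`scalar_mul`."""
    _check_rung(q)
    if eps < 0:
        raise DomainError(f"exponent must be non-negative, got {eps}")
    a, b, c, d = R.unit()
    nc = _one_minus_pow(c ** q, eps) ** (1.0 / q)
    nd = _one_minus_pow(d ** q, eps) ** (1.0 / q)
    return TLIVqROFN.from_unit(_pow(a, eps), _pow(b, eps), nc, nd, R.scale)


def complement(R: TLIVqROFN) -> TLIVqROFN:
    """Swap membership and non-membership intervals; an involution."""
    return TLIVqROFN(R.u, R.y, R.r, R.t, R.scale)


def hamming(R1: TLIVqROFN, R2: TLIVqROFN, q: float) -> float:
    """Normalized Hamming distance on the unit scale, in [0, 1].

    d = 1/4 * sum over the four components of |x1^q - x2^q|.
    """
    _check_rung(q)
    _check_compatible(R1, R2)
    u1 = R1.unit()
    u2 = R2.unit()
    return 0.25 * sum(abs(x1 ** q - x2 ** q) for x1, x2 in zip(u1, u2))


def hamming_two_tuple(R1: TLIVqROFN, R2: TLIVqROFN, q: float) -> TwoTuple:
    """The distance expressed linguistically as Delta(tau * d)."""
    return delta(R1.scale.tau * hamming(R1, R2, q), R1.scale)


def validate_all(
    elements: Iterable[tuple[str, TLIVqROFN]], q: float, mode: str = "warn"
) -> list[str]:
    """Validate a labelled collection; returns the diagnostics gathered."""
    messages: list[str] = []
    for label, R in elements:
        report = validate(R, q, mode=mode, label=label)
        messages.extend(report.messages)
    return messages
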