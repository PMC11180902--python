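"""Weighted averaging and weighted geometric aggregation operators.

Both operators are given in closed form (the product formulas) and as folds
of the elementary operational laws; the two routes agree to floating-point
accuracy, which the test suite exercises as the module's central oracle.

Weight handling deserves a note.  Theory requires the weights to sum to 1,
but published studies sometimes carry weight vectors that do not (expert
weights elicited independently, for instance).  Three policies are offered:

``as-given``
    use the weights verbatim; a warning is logged when they do not sum to 1
    (default — keeps published inputs reproducible while surfacing the
    discrepancy);
``renormalize``
    divide by the sum;
``strict``
    raise when the sum deviates from 1 beyond the tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import reduce
from typing import Sequence

from .algebra import TLIVqROFN, add, mul, power, scalar_mul, _clamp01, _pow
from .errors import DimensionError, DomainError, WeightPolicyError

__all__ = ["WeightVector", "wa", "wg", "wa_fold", "wg_fold", "equal_weight_geometric_mean"]

logger = logging.getLogger("tlmabac")

POLICIES = ("as-given", "renormalize", "strict")


def _wlog1p_pow(x: float, q: float, wj: float) -> float:
    """w * log(1 - x^q), with zero weights contributing exactly nothing."""
    if wj == 0.0:
        return 0.0
    if x >= 1.0:
        return -math.inf
    return wj * math.log1p(-(x ** q))


@dataclass(frozen=True)
class WeightVector:
    """An ordered vector of weights in [0, 1] with a sum policy."""

    weights: tuple[float, ...]
    policy: str = "as-given"
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.policy not in POLICIES:
            raise DomainError(f"unknown weight policy {self.policy!r}")
        for w in self.weights:
            if not (0.0 <= w <= 1.0):
                raise DomainError(f"weights must lie in [0, 1], got {w}")

    def __len__(self) -> int:
        return len(self.weights)

    def resolve(self) -> tuple[float, ...]:
        """Apply the sum policy and return the effective weights."""
        total = math.fsum(self.weights)
        off = abs(total - 1.0)
        if off <= self.tolerance:
            return self.weights
        if self.policy == "strict":
            raise WeightPolicyError(
                f"weights sum to {total:.6f}, not 1 (policy 'strict')"
            )
        if self.policy == "renormalize":
            if total == 0:
                raise WeightPolicyError("cannot renormalize an all-zero weight vector")
            return tuple(w / total for w in self.weights)
        logger.warning(
            "weights sum to %.6f, not 1; using them as given (policy 'as-given')",
            total,
        )
        return self.weights


def _as_weights(w: "WeightVector | Sequence[float]") -> WeightVector:
    if isinstance(w, WeightVector):
        return w
    return WeightVector(tuple(w))


def _check_inputs(elements: Sequence[TLIVqROFN], weights: Sequence[float]) -> None:
    if not elements:
        raise DimensionError("cannot aggregate an empty collection")
    if len(elements) != len(weights):
        raise DimensionError(
            f"{len(elements)} elements but {len(weights)} weights"
        )
    tau = elements[0].scale.tau
    for R in elements[1:]:
        if R.scale.tau != tau:
            raise DimensionError("elements do not share one linguistic scale")


def wa(
    elements: Sequence[TLIVqROFN],
    w: "WeightVector | Sequence[float]",
    q: float,
) -> TLIVqROFN:
    """Weighted averaging operator (closed form).

    Membership endpoints: (1 - prod_j (1 - a_j^q)^{w_j})^{1/q};
    non-membership endpoints: prod_j c_j^{w_j}.
    """
    weights = _as_weights(w).resolve()
    _check_inputs(elements, weights)
    scale = elements[0].scale
    # log-space accumulation of prod (1 - x^q)^w avoids cancellation when
    # the complementary products stay close to 1 (tiny x^q at large rungs)
    la = lb = 0.0
    pc = pd = 1.0
    for R, wj in zip(elements, weights):
        a, b, c, d = R.unit()
        la += _wlog1p_pow(a, q, wj)
        lb += _wlog1p_pow(b, q, wj)
        pc *= _pow(c, wj)
        pd *= _pow(d, wj)
    a = _clamp01(-math.expm1(la)) ** (1.0 / q)
    b = _clamp01(-math.expm1(lb)) ** (1.0 / q)
    return TLIVqROFN.from_unit(a, b, pc, pd, scale)


def wg(
    elements: Sequence[TLIVqROFN],
    w: "WeightVector | Sequence[float]",
    q: float,
) -> TLIVqROFN:
    """Weighted geometric operator (closed form): dual of :func:`wa`.

    Membership endpoints: prod_j a_j^{w_j}; non-membership endpoints:
    (1 - prod_j (1 - c_j^q)^{w_j})^{1/q}.  In the originating literature
    this operator also appears under the initialisms WJ and WG; this module
    uses WG throughout.
    """
    weights = _as_weights(w).resolve()
    _check_inputs(elements, weights)
    scale = elements[0].scale
    pa = pb = 1.0
    lc = ld = 0.0
    for R, wj in zip(elements, weights):
        a, b, c, d = R.unit()
        pa *= _pow(a, wj)
        pb *= _pow(b, wj)
        lc += _wlog1p_pow(c, q, wj)
        ld += _wlog1p_pow(d, q, wj)
    c = _clamp01(-math.expm1(lc)) ** (1.0 / q)
    d = _clamp01(-math.expm1(ld)) ** (1.0 / q)
    return TLIVqROFN.from_unit(pa, pb, c, d, scale)


def wa_fold(
    elements: Sequence[TLIVqROFN],
    w: "WeightVector | Sequence[float]",
    q: float,
) -> TLIVqROFN:
    """Weighted average as the fold (+)_j w_j R_j of the operational laws.

    Mathematically identical to :func:`wa`; kept as an independent route for
    cross-checking the closed form.
    """
    weights = _as_weights(w).resolve()
    _check_inputs(elements, weights)
    terms = [scalar_mul(wj, R, q) for R, wj in zip(elements, weights)]
    return reduce(lambda x, y: add(x, y, q), terms)


def wg_fold(
    elements: Sequence[TLIVqROFN],
    w: "WeightVector | Sequence[float]",
    q: float,
) -> TLIVqROFN:
    """Weighted geometric mean as the fold (x)_j R_j^{w_j}."""
    weights = _as_weights(w).resolve()
    _check_inputs(elements, weights)
    terms = [power(R, wj, q) for R, wj in zip(elements, weights)]
    return reduce(lambda x, y: mul(x, y, q), terms)


def equal_weight_geometric_mean(
    elements: Sequence[TLIVqROFN], q: float
) -> TLIVqROFN:
    """Geometric mean with uniform weights 1/n (the border-area builder)."""
    if not elements:
        raise DimensionError("cannot aggregate an empty collection")
    n = len(elements)
    return wg(elements, WeightVector((1.0 / n,) * n), q)
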