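"""The 2-tuple linguistic representation model.

A linguistic term set L = {J_0, ..., J_tau} discretizes a qualitative scale
into tau+1 ordered labels.  The 2-tuple model represents any *continuous*
value xi in [0, tau] losslessly as a pair (J_ell, upsilon): the nearest term
index ell = round(xi) together with the *symbolic translation*
upsilon = xi - ell in [-0.5, 0.5).  The conversion functions
:func:`delta` and :func:`delta_inv` are mutually inverse, so aggregation can
be carried out on the real line and re-expressed linguistically without
information loss.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import DomainError, FormatError

__all__ = ["LinguisticScale", "TwoTuple", "delta", "delta_inv"]


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered linguistic term set with granularity bound ``tau``.

    Terms are indexed 0..tau (tau+1 terms).  ``labels``, when given, names
    each term in order.
    """

    tau: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.tau < 2:
            raise DomainError(f"scale granularity tau must be >= 2, got {self.tau}")
        if self.labels is not None:
            labels = tuple(self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != self.tau + 1:
                raise DomainError(
                    f"expected {self.tau + 1} labels for tau={self.tau}, "
                    f"got {len(labels)}"
                )

    def label(self, ell: int) -> str:
        if self.labels is None:
            return f"J{ell}"
        return self.labels[ell]


@dataclass(frozen=True, order=False)
class TwoTuple:
    """A linguistic 2-tuple (J_ell, upsilon).

    ``ell`` is the term index and ``upsilon`` the symbolic translation in
    [-0.5, 0.5).  The equivalent real value is ``ell + upsilon``.
    """

    ell: int
    upsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.ell < 0:
            raise DomainError(f"term index must be non-negative, got {self.ell}")
        if not (-0.5 <= self.upsilon < 0.5):
            raise DomainError(
                f"symbolic translation must lie in [-0.5, 0.5), got {self.upsilon}"
            )
        if self.ell + self.upsilon < 0:
            raise DomainError(
                f"2-tuple value {self.ell} + {self.upsilon} falls below 0"
            )

    @property
    def value(self) -> float:
        return self.ell + self.upsilon

    @classmethod
    def parse(cls, text: str) -> "TwoTuple":
        """Parse ``"J3"`` (crisp) or ``"(J3, 0.4154)"`` forms.

        The unicode minus occasionally found in published tables is
        normalized to the ASCII hyphen.
        """
        s = text.strip().replace("−", "-")
        m = re.fullmatch(r"J(\d+)", s)
        if m:
            return cls(int(m.group(1)), 0.0)
        m = re.fullmatch(r"\(\s*J(\d+)\s*,\s*(-?\d+(?:\.\d+)?)\s*\)", s)
        if m:
            return cls(int(m.group(1)), float(m.group(2)))
        raise FormatError(f"cannot parse 2-tuple from {text!r}")

    def __str__(self) -> str:
        if self.upsilon == 0:
            return f"J{self.ell}"
        return f"(J{self.ell}, {self.upsilon:.4f})"


def delta(xi: float, scale: LinguisticScale) -> TwoTuple:
    """Encode a real ``xi`` in [0, tau] as a 2-tuple.

    The term index is obtained by rounding half *up* (toward the larger
    index), which keeps the translation in [-0.5, 0.5); at xi = tau the
    result is (J_tau, 0).
    """
    tau = scale.tau
    if not (0 <= xi <= tau):
        raise DomainError(f"value {xi!r} outside the scale range [0, {tau}]")
    ell = math.floor(xi + 0.5)
    if ell > tau:
        ell = tau
    return TwoTuple(int(ell), xi - ell)


def delta_inv(tt: TwoTuple, scale: LinguisticScale | None = None) -> float:
    """Decode a 2-tuple back to its real value ell + upsilon."""
    xi = tt.value
    if scale is not None and not (0 <= xi <= scale.tau):
        raise DomainError(
            f"2-tuple {tt} decodes to {xi}, outside [0, {scale.tau}]"
        )
    return xi
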