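"""Synthetic decision-problem generator.

Produces random expert x alternative x attribute cubes of valid fuzzy
numbers for property testing and benchmarking.  Interval endpoints are
drawn as term indices (optionally with continuous symbolic translations);
in ``enforce`` mode each entry is rejection-sampled until the rung-q
constraint (t/tau)^q + (y/tau)^q <= 1 holds, so generated instances are
valid under strict validation.  Generation is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebra import TLIVqROFN
from .errors import DomainError, InfeasibleSpecError
from .linguistic import LinguisticScale
from .mabac import DecisionCube

__all__ = ["GeneratorSpec", "generate_cube", "generate_number"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Dimensions and distributional knobs of a synthetic instance.

    ``crisp`` draws plain term indices (the form raw expert judgements take);
    otherwise endpoints get uniform symbolic translations.  ``max_width``
    bounds the sampled interval widths in term steps.
    """

    n_experts: int = 4
    n_alternatives: int = 7
    n_attributes: int = 4
    tau: int = 8
    q: float = 6.0
    seed: int = 0
    constraint: str = "enforce"  # enforce | off
    crisp: bool = True
    max_width: int = 2
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_experts, self.n_alternatives, self.n_attributes) < 1:
            raise DomainError("all cube dimensions must be at least 1")
        if self.tau < 2:
            raise DomainError(f"tau must be >= 2, got {self.tau}")
        if not self.q > 0:
            raise DomainError(f"rung q must be positive, got {self.q}")
        if self.constraint not in ("enforce", "off"):
            raise DomainError(f"unknown constraint mode {self.constraint!r}")
        if self.max_width < 0:
            raise DomainError("max_width must be non-negative")


def _sample_interval(rng: np.random.Generator, spec: GeneratorSpec) -> tuple[float, float]:
    lo = int(rng.integers(0, spec.tau + 1))
    hi = min(spec.tau, lo + int(rng.integers(0, spec.max_width + 1)))
    if spec.crisp:
        return float(lo), float(hi)
    a = lo + rng.uniform(-0.5, 0.5)
    b = hi + rng.uniform(-0.5, 0.5)
    a, b = sorted((min(max(a, 0.0), spec.tau), min(max(b, 0.0), spec.tau)))
    return a, b


def generate_number(
    rng: np.random.Generator, spec: GeneratorSpec, scale: LinguisticScale
) -> TLIVqROFN:
    """Draw one valid fuzzy number per the spec (rejection sampling)."""
    for _ in range(spec.max_rejections):
        r, t = _sample_interval(rng, spec)
        u, y = _sample_interval(rng, spec)
        if spec.constraint == "enforce":
            if (t / spec.tau) ** spec.q + (y / spec.tau) ** spec.q > 1.0:
                continue
        return TLIVqROFN.from_xi(r, t, u, y, scale)
    raise InfeasibleSpecError(
        f"no valid sample within {spec.max_rejections} rejections "
        f"(q={spec.q}, tau={spec.tau}): the rung constraint may be infeasible "
        "for this term distribution"
    )


def generate_cube(spec: GeneratorSpec) -> DecisionCube:
    """Generate a reproducible random decision cube."""
    rng = np.random.default_rng(spec.seed)
    scale = LinguisticScale(spec.tau)
    entries = [
        [
            [generate_number(rng, spec, scale) for _ in range(spec.n_attributes)]
            for _ in range(spec.n_alternatives)
        ]
        for _ in range(spec.n_experts)
    ]
    return DecisionCube.build(entries)
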