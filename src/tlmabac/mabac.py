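"""The extended MABAC group-decision pipeline.

MABAC (multi-attributive border approximation area comparison) ranks a set
of alternatives by their signed distance to a per-attribute *border
approximation area* (BAA).  The pipeline stages are

1. collect one fuzzy decision matrix per expert;
2. aggregate the expert matrices with the weighted averaging operator and
   the expert weights;
3. normalize: benefit attributes pass through, cost attributes are
   complemented (membership and non-membership swapped);
4. scale each column by its attribute weight (scalar multiplication law);
5. build the BAA vector g as the per-column geometric mean over
   alternatives (exponent 1/alpha);
6. form the signed normalized Hamming distance of every weighted element to
   its column's BAA element, the sign taken from the score/accuracy
   comparison;
7. sum distances per alternative into the cumulative value S and rank by
   descending S.

A pipeline run can also *enter at stage 3* with a precomputed aggregated
matrix, which is how published intermediate tables are reproduced exactly
even when the expert-aggregation inputs behind them are not fully
recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from .aggregation import WeightVector, equal_weight_geometric_mean, wa
from .algebra import TLIVqROFN, compare, complement, hamming, score, validate_all
from .errors import DimensionError, DomainError
from .linguistic import LinguisticScale

__all__ = [
    "DecisionCube",
    "PipelineConfig",
    "MabacResult",
    "aggregate_experts",
    "normalize",
    "weight_matrix",
    "compute_baa",
    "distance_matrix",
    "cumulative_scores",
    "rank",
    "run_pipeline",
    "sensitivity_sweep",
]

Matrix = list[list[TLIVqROFN]]

#: scores within this band of the border element give an exact-zero distance
SIGN_TIE_TOL = 1e-9


@dataclass(frozen=True)
class DecisionCube:
    """experts x alternatives x attributes array of fuzzy numbers."""

    entries: tuple[tuple[tuple[TLIVqROFN, ...], ...], ...]
    expert_ids: tuple[str, ...]
    alternative_ids: tuple[str, ...]
    attribute_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        f, alpha, beta = self.shape
        if len(self.expert_ids) != f:
            raise DimensionError("expert_ids length does not match the cube")
        for mat in self.entries:
            if len(mat) != alpha or any(len(row) != beta for row in mat):
                raise DimensionError("ragged decision cube")
        if len(self.alternative_ids) != alpha or len(self.attribute_ids) != beta:
            raise DimensionError("id lists do not match the cube dimensions")
        tau = self.scale.tau
        for mat in self.entries:
            for row in mat:
                for R in row:
                    if R.scale.tau != tau:
                        raise DimensionError("cube entries on mixed scales")

    @classmethod
    def build(
        cls,
        entries: Sequence[Sequence[Sequence[TLIVqROFN]]],
        expert_ids: Sequence[str] | None = None,
        alternative_ids: Sequence[str] | None = None,
        attribute_ids: Sequence[str] | None = None,
    ) -> "DecisionCube":
        f = len(entries)
        alpha = len(entries[0]) if f else 0
        beta = len(entries[0][0]) if alpha else 0
        return cls(
            tuple(tuple(tuple(row) for row in mat) for mat in entries),
            tuple(expert_ids) if expert_ids else tuple(f"E{i+1}" for i in range(f)),
            tuple(alternative_ids)
            if alternative_ids
            else tuple(f"A{i+1}" for i in range(alpha)),
            tuple(attribute_ids)
            if attribute_ids
            else tuple(f"C{j+1}" for j in range(beta)),
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        f = len(self.entries)
        alpha = len(self.entries[0]) if f else 0
        beta = len(self.entries[0][0]) if alpha else 0
        return f, alpha, beta

    @property
    def scale(self) -> LinguisticScale:
        return self.entries[0][0][0].scale


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs besides the decision data."""

    q: float
    scale: LinguisticScale
    expert_weights: WeightVector
    attribute_weights: WeightVector
    attribute_kinds: tuple[str, ...]
    validation_mode: str = "warn"

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise DomainError(f"rung q must be positive, got {self.q}")
        for kind in self.attribute_kinds:
            if kind not in ("benefit", "cost"):
                raise DomainError(f"unknown attribute kind {kind!r}")


@dataclass(frozen=True)
class MabacResult:
    """All pipeline intermediates plus the final ranking."""

    config: PipelineConfig
    alternative_ids: tuple[str, ...]
    attribute_ids: tuple[str, ...]
    aggregated: Matrix
    normalized: Matrix
    weighted: Matrix
    baa: list[TLIVqROFN]
    distances: list[list[float]]
    cumulative: list[float]
    ranking: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def scores(self) -> list[list[float]]:
        """Unit-scale scores of the weighted normalized matrix."""
        q = self.config.q
        return [[score(R, q) for R in row] for row in self.weighted]

    @property
    def baa_scores(self) -> list[float]:
        return [score(g, self.config.q) for g in self.baa]


def aggregate_experts(cube: DecisionCube, cfg: PipelineConfig) -> Matrix:
    """Pool the expert matrices entrywise with the WA operator."""
    f, alpha, beta = cube.shape
    if len(cfg.expert_weights) != f:
        raise DimensionError(
            f"{f} experts but {len(cfg.expert_weights)} expert weights"
        )
    # resolve once so a weight-policy warning is logged once, not per cell
    eff = WeightVector(cfg.expert_weights.resolve(), tolerance=float("inf"))
    return [
        [
            wa([cube.entries[g][i][j] for g in range(f)], eff, cfg.q)
            for j in range(beta)
        ]
        for i in range(alpha)
    ]


def normalize(matrix: Matrix, kinds: Sequence[str]) -> Matrix:
    """Pass benefit columns through; complement cost columns."""
    if matrix and len(kinds) != len(matrix[0]):
        raise DimensionError(
            f"{len(matrix[0])} attributes but {len(kinds)} kind flags"
        )
    for kind in kinds:
        if kind not in ("benefit", "cost"):
            raise DomainError(f"unknown attribute kind {kind!r}")
    return [
        [R if kind == "benefit" else complement(R) for R, kind in zip(row, kinds)]
        for row in matrix
    ]


def weight_matrix(
    matrix: Matrix, weights: "WeightVector | Sequence[float]", q: float
) -> Matrix:
    """Scale column j by the attribute weight via the scalar-multiplication law."""
    from .algebra import scalar_mul

    w = weights.resolve() if isinstance(weights, WeightVector) else tuple(weights)
    if matrix and len(w) != len(matrix[0]):
        raise DimensionError(f"{len(matrix[0])} attributes but {len(w)} weights")
    return [[scalar_mul(wj, R, q) for R, wj in zip(row, w)] for row in matrix]


def compute_baa(weighted: Matrix, q: float) -> list[TLIVqROFN]:
    """Border approximation area: per-column geometric mean over alternatives."""
    if not weighted:
        raise DimensionError("empty weighted matrix")
    beta = len(weighted[0])
    return [
        equal_weight_geometric_mean([row[j] for row in weighted], q)
        for j in range(beta)
    ]


def distance_matrix(
    weighted: Matrix, baa: Sequence[TLIVqROFN], q: float
) -> list[list[float]]:
    """Signed normalized Hamming distances to the border elements.

    Positive where the element outranks its border element (score, then
    accuracy), negative where it falls below, exactly zero on a tie.
    """
    if weighted and len(baa) != len(weighted[0]):
        raise DimensionError("BAA length does not match the attribute count")
    out: list[list[float]] = []
    for row in weighted:
        drow = []
        for R, g in zip(row, baa):
            side = compare(R, g, q, tol=SIGN_TIE_TOL)
            drow.append(0.0 if side == 0 else side * hamming(R, g, q))
        out.append(drow)
    return out


def cumulative_scores(distances: Sequence[Sequence[float]]) -> list[float]:
    """Row sums of the signed distance matrix."""
    return [sum(row) for row in distances]


def rank(
    cumulative: Sequence[float], alternative_ids: Sequence[str] | None = None
) -> tuple[str, ...]:
    """Alternatives by descending cumulative value; ties stable by index."""
    n = len(cumulative)
    ids = tuple(alternative_ids) if alternative_ids else tuple(
        f"A{i+1}" for i in range(n)
    )
    order = sorted(range(n), key=lambda i: (-cumulative[i], i))
    return tuple(ids[i] for i in order)


def run_pipeline(
    cube: DecisionCube | None,
    cfg: PipelineConfig,
    entry_stage: Literal["experts", "aggregated"] = "experts",
    aggregated: Matrix | None = None,
    alternative_ids: Sequence[str] | None = None,
    attribute_ids: Sequence[str] | None = None,
) -> MabacResult:
    """Execute the pipeline from the chosen entry stage onward.

    ``entry_stage="experts"`` starts from the per-expert cube;
    ``entry_stage="aggregated"`` skips expert pooling and takes the supplied
    alternatives x attributes ``aggregated`` matrix as the stage-2 output.
    """
    warnings: list[str] = []
    if entry_stage == "experts":
        if cube is None:
            raise DomainError("entry stage 'experts' requires a decision cube")
        f, alpha, beta = cube.shape
        labelled = [
            (
                f"({cube.expert_ids[g]}, {cube.alternative_ids[i]}, "
                f"{cube.attribute_ids[j]})",
                cube.entries[g][i][j],
            )
            for g in range(f)
            for i in range(alpha)
            for j in range(beta)
        ]
        warnings.extend(validate_all(labelled, cfg.q, cfg.validation_mode))
        agg = aggregate_experts(cube, cfg)
        alt_ids = cube.alternative_ids
        attr_ids = cube.attribute_ids
    elif entry_stage == "aggregated":
        if aggregated is None:
            raise DomainError("entry stage 'aggregated' requires the matrix")
        agg = [list(row) for row in aggregated]
        alpha = len(agg)
        beta = len(agg[0]) if alpha else 0
        alt_ids = (
            tuple(alternative_ids)
            if alternative_ids
            else tuple(f"A{i+1}" for i in range(alpha))
        )
        attr_ids = (
            tuple(attribute_ids)
            if attribute_ids
            else tuple(f"C{j+1}" for j in range(beta))
        )
        labelled = [
            (f"({alt_ids[i]}, {attr_ids[j]})", agg[i][j])
            for i in range(alpha)
            for j in range(beta)
        ]
        warnings.extend(validate_all(labelled, cfg.q, cfg.validation_mode))
    else:
        raise DomainError(f"unknown entry stage {entry_stage!r}")

    if len(cfg.attribute_kinds) != beta:
        raise DimensionError(
            f"{beta} attributes but {len(cfg.attribute_kinds)} kind flags"
        )
    norm = normalize(agg, cfg.attribute_kinds)
    weighted = weight_matrix(norm, cfg.attribute_weights, cfg.q)
    baa = compute_baa(weighted, cfg.q)
    distances = distance_matrix(weighted, baa, cfg.q)
    cumulative = cumulative_scores(distances)
    ranking = rank(cumulative, alt_ids)
    return MabacResult(
        config=cfg,
        alternative_ids=alt_ids,
        attribute_ids=attr_ids,
        aggregated=agg,
        normalized=norm,
        weighted=weighted,
        baa=baa,
        distances=distances,
        cumulative=cumulative,
        ranking=ranking,
        warnings=tuple(warnings),
    )


def sensitivity_sweep(
    cfg: PipelineConfig,
    q_values: Sequence[float],
    cube: DecisionCube | None = None,
    entry_stage: Literal["experts", "aggregated"] = "experts",
    aggregated: Matrix | None = None,
    alternative_ids: Sequence[str] | None = None,
) -> list[dict]:
    """Rerun the pipeline for each rung q and collect S vectors and rankings.

    Runs in ``warn`` validation mode regardless of the configured mode,
    since small rungs commonly violate the rung constraint on data that was
    elicited at a larger q; the violations are reported, not fatal.
    Returns one record per q: ``{"q", "cumulative", "ranking", "top"}``.
    """
    records = []
    for q in q_values:
        if not q > 0:
            raise DomainError(f"rung q must be positive, got {q}")
        run_cfg = replace(cfg, q=q, validation_mode="warn")
        result = run_pipeline(
            cube,
            run_cfg,
            entry_stage=entry_stage,
            aggregated=aggregated,
            alternative_ids=alternative_ids,
        )
        records.append(
            {
                "q": q,
                "cumulative": list(result.cumulative),
                "ranking": list(result.ranking),
                "top": result.ranking[0],
            }
        )
    return records
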