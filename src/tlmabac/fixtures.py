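"""Embedded case study: breast-cancer treatment selection.

Seven treatment alternatives (lumpectomy, mastectomy, chemotherapy, hormone
therapy, targeted therapy, immunotherapy, clinical trials) are judged by
four medical experts against four attributes (cancer stage/subtype, patient
preferences, resource availability, expected outcomes) on a 9-term
linguistic scale (tau = 8) at rung q = 6.  All attributes are benefit-type.

The fixture ships every published intermediate: the four expert matrices,
the aggregated matrix, the weighted normalized matrix and its scores, the
border approximation area (BAA) vector with its scores, the signed distance
matrix, the cumulative values and the final ranking.

A caveat on provenance: re-aggregating the expert matrices with the stated
expert weights (which sum to 0.8162, not 1) does not reproduce the published
aggregated matrix under any weight policy, so the downstream stages are
anchored on the published aggregated matrix (pipeline entry stage
``"aggregated"``); :func:`expert_aggregation_deviation` quantifies the
discrepancy instead of hiding it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .aggregation import WeightVector
from .algebra import TLIVqROFN
from .errors import DomainError
from .linguistic import LinguisticScale
from .mabac import DecisionCube, PipelineConfig, aggregate_experts

__all__ = ["FixtureSet", "breast_cancer", "expert_aggregation_deviation"]

CASES = ("breast-cancer",)


@dataclass(frozen=True)
class FixtureSet:
    """The published tables of one worked case study, as domain objects."""

    case: str
    scale: LinguisticScale
    config: PipelineConfig
    cube: DecisionCube
    aggregated: list[list[TLIVqROFN]]
    weighted: list[list[TLIVqROFN]]
    weighted_scores: list[list[float]]
    baa: list[TLIVqROFN]
    baa_scores: list[float]
    distances: list[list[float]]
    cumulative: list[float]
    ranking: tuple[str, ...]

    @property
    def alternative_ids(self) -> tuple[str, ...]:
        return self.cube.alternative_ids

    @property
    def attribute_ids(self) -> tuple[str, ...]:
        return self.cube.attribute_ids


def _load_doc(case: str) -> dict:
    name = case.replace("-", "_") + ".json"
    text = resources.files("tlmabac.data").joinpath(name).read_text(encoding="utf-8")
    return json.loads(text)


def breast_cancer(weight_policy: str = "as-given") -> FixtureSet:
    """Load the breast-cancer treatment-selection case study."""
    return _load_case("breast-cancer", weight_policy)


def _load_case(case: str, weight_policy: str = "as-given") -> FixtureSet:
    if case not in CASES:
        raise DomainError(f"unknown case {case!r}; available: {CASES}")
    from .io import number_from_json

    doc = _load_doc(case)
    scale = LinguisticScale(int(doc["tau"]), tuple(doc["labels"]))
    cfg = PipelineConfig(
        q=float(doc["q"]),
        scale=scale,
        expert_weights=WeightVector(tuple(doc["expert_weights"]), policy=weight_policy),
        attribute_weights=WeightVector(
            tuple(doc["attribute_weights"]), policy=weight_policy
        ),
        attribute_kinds=tuple(doc["attribute_kinds"]),
        validation_mode="warn",
    )

    def mat(key: str) -> list[list[TLIVqROFN]]:
        return [
            [number_from_json(cell, scale, where=f"{key}[{i}][{j}]")
             for j, cell in enumerate(row)]
            for i, row in enumerate(doc[key])
        ]

    cube = DecisionCube.build(
        [
            [
                [
                    number_from_json(cell, scale, where=f"cube[{g}][{i}][{j}]")
                    for j, cell in enumerate(row)
                ]
                for i, row in enumerate(matrix)
            ]
            for g, matrix in enumerate(doc["cube"])
        ],
        expert_ids=doc["expert_ids"],
        alternative_ids=doc["alternative_ids"],
        attribute_ids=doc["attribute_ids"],
    )
    return FixtureSet(
        case=case,
        scale=scale,
        config=cfg,
        cube=cube,
        aggregated=mat("aggregated"),
        weighted=mat("weighted"),
        weighted_scores=[list(map(float, r)) for r in doc["weighted_scores"]],
        baa=[
            number_from_json(g, scale, where=f"baa[{j}]")
            for j, g in enumerate(doc["baa"])
        ],
        baa_scores=[float(x) for x in doc["baa_scores"]],
        distances=[list(map(float, r)) for r in doc["distances"]],
        cumulative=[float(x) for x in doc["cumulative"]],
        ranking=tuple(doc["ranking"]),
    )


def expert_aggregation_deviation(
    fixture: FixtureSet, weight_policy: str = "as-given"
) -> dict:
    """Re-aggregate the expert cube and report deviations from the published
    aggregated matrix.

    Returns per-cell maximum absolute deviation of the four real components
    plus the overall maximum — a diagnostic, not an assertion: the published
    expert weights do not sum to 1 and the published aggregate is not
    recoverable from them.
    """
    cfg = fixture.config
    cfg = PipelineConfig(
        q=cfg.q,
        scale=cfg.scale,
        expert_weights=WeightVector(
            cfg.expert_weights.weights, policy=weight_policy
        ),
        attribute_weights=cfg.attribute_weights,
        attribute_kinds=cfg.attribute_kinds,
        validation_mode="warn",
    )
    recomputed = aggregate_experts(fixture.cube, cfg)
    cells = []
    worst = 0.0
    for i, (rrow, prow) in enumerate(zip(recomputed, fixture.aggregated)):
        for j, (Rc, Rp) in enumerate(zip(rrow, prow)):
            dev = max(abs(x - y) for x, y in zip(Rc.xi(), Rp.xi()))
            worst = max(worst, dev)
            cells.append(
                {
                    "alternative": fixture.alternative_ids[i],
                    "attribute": fixture.attribute_ids[j],
                    "max_component_deviation": dev,
                }
            )
    return {
        "weight_policy": weight_policy,
        "weight_sum": sum(cfg.expert_weights.weights),
        "max_deviation": worst,
        "cells": cells,
    }
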