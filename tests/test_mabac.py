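"""The MABAC pipeline: stage behaviour, case-study regression, sweeps."""

import pytest

from tlmabac import (
    DecisionCube,
    GeneratorSpec,
    PipelineConfig,
    TLIVqROFN,
    WeightVector,
    aggregate_experts,
    complement,
    compute_baa,
    cumulative_scores,
    distance_matrix,
    generate_cube,
    normalize,
    rank,
    run_pipeline,
    score,
    sensitivity_sweep,
    weight_matrix,
)
from tlmabac.errors import DimensionError, DomainError
from tlmabac.fixtures import expert_aggregation_deviation


def max_matrix_dev(got, expected):
    return max(
        abs(x - y)
        for grow, erow in zip(got, expected)
        for G, E in zip(grow, erow)
        for x, y in zip(G.xi(), E.xi())
    )


# ------------------------------------------------------------------ stages


def test_normalize_benefit_passthrough_and_cost_complement(case):
    matrix = case.aggregated
    assert normalize(matrix, ["benefit"] * 4) == [list(r) for r in matrix]
    cost = normalize(matrix, ["cost"] * 4)
    assert cost[0][0] == complement(matrix[0][0])
    # complement is an involution, so normalizing cost columns twice is id
    again = normalize(cost, ["cost"] * 4)
    assert again == [list(r) for r in matrix]
    with pytest.raises(DomainError):
        normalize(matrix, ["benefit", "cost", "benefit", "loss"])


def test_weight_matrix_reproduces_published_weighted_matrix(case):
    got = weight_matrix(case.aggregated, case.config.attribute_weights, case.config.q)
    assert max_matrix_dev(got, case.weighted) < 5e-4


def test_weight_one_leaves_column_unchanged(case):
    got = weight_matrix(case.aggregated, (1.0, 1.0, 1.0, 1.0), case.config.q)
    assert max_matrix_dev(got, case.aggregated) < 1e-12


def test_scores_reproduce_published_table(case):
    # 1e-4: published scores carry their own last-digit rounding on top of
    # the 4-decimal rounding of the published matrix they derive from
    q = case.config.q
    for row, expected in zip(case.weighted, case.weighted_scores):
        for R, e in zip(row, expected):
            assert score(R, q) == pytest.approx(e, abs=1e-4)


def test_baa_reproduces_published_vector(case):
    got = compute_baa(case.weighted, case.config.q)
    for G, E in zip(got, case.baa):
        assert G.xi() == pytest.approx(E.xi(), abs=5e-4)
    for G, e in zip(got, case.baa_scores):
        assert score(G, case.config.q) == pytest.approx(e, abs=5e-5)


def test_baa_of_single_row_is_that_row(case):
    row = case.weighted[2]
    got = compute_baa([row], case.config.q)
    assert max_matrix_dev([got], [row]) < 1e-9


def test_distances_reproduce_published_matrix_with_signs(case):
    D = distance_matrix(case.weighted, case.baa, case.config.q)
    for drow, erow in zip(D, case.distances):
        for d, e in zip(drow, erow):
            assert d == pytest.approx(e, abs=5e-5)
            if abs(e) > 1e-12:
                assert (d > 0) == (e > 0)


def test_distance_of_border_to_itself_is_zero(case):
    D = distance_matrix([list(case.baa)], case.baa, case.config.q)
    assert D[0] == [0.0] * 4


def test_distance_sign_flips_under_role_swap(case):
    q = case.config.q
    fwd = distance_matrix(case.weighted, case.baa, q)
    for j in range(4):
        col = [[row[j]] for row in case.weighted]
        for i, cell in enumerate(col):
            back = distance_matrix([[case.baa[j]]], [cell[0]], q)[0][0]
            assert back == pytest.approx(-fwd[i][j], abs=1e-12)


def test_cumulative_and_rank(case):
    D = distance_matrix(case.weighted, case.baa, case.config.q)
    S = cumulative_scores(D)
    for s, e in zip(S, case.cumulative):
        assert s == pytest.approx(e, abs=2e-4)
    assert rank(S, case.alternative_ids) == case.ranking
    assert rank([0.0, 0.0, 0.0]) == ("A1", "A2", "A3")  # stable tie-break
    assert rank([-s for s in S], case.alternative_ids) == tuple(
        reversed(case.ranking)
    )
    assert cumulative_scores([[0.0] * 4] * 3) == [0.0, 0.0, 0.0]


# --------------------------------------------------------------- aggregation


def make_identical_cube(scale, R, f=3, alpha=2, beta=2):
    return DecisionCube.build([[[R] * beta] * alpha] * f)


def test_aggregate_identical_experts_is_identity(scale8):
    R = TLIVqROFN.from_indices(2, 3, 4, 5, scale8)
    cube = make_identical_cube(scale8, R)
    cfg = PipelineConfig(
        q=6,
        scale=scale8,
        expert_weights=WeightVector((0.5, 0.3, 0.2)),
        attribute_weights=WeightVector((0.6, 0.4)),
        attribute_kinds=("benefit", "benefit"),
    )
    agg = aggregate_experts(cube, cfg)
    for row in agg:
        for G in row:
            assert G.xi() == pytest.approx(R.xi(), abs=1e-9)


def test_single_expert_unit_weight_is_identity(scale8):
    cube = generate_cube(GeneratorSpec(n_experts=1, n_alternatives=3,
                                       n_attributes=2, seed=11))
    cfg = PipelineConfig(
        q=6,
        scale=scale8,
        expert_weights=WeightVector((1.0,)),
        attribute_weights=WeightVector((0.5, 0.5)),
        attribute_kinds=("benefit", "benefit"),
    )
    agg = aggregate_experts(cube, cfg)
    assert max_matrix_dev(agg, cube.entries[0]) < 1e-9


def test_published_expert_aggregation_is_not_reproducible(case):
    """The published expert weights sum to 0.8162 and do not regenerate the
    published aggregated matrix under either policy; the deviation report
    documents this rather than asserting agreement."""
    for policy in ("as-given", "renormalize"):
        report = expert_aggregation_deviation(case, policy)
        assert report["max_deviation"] > 5e-4
        assert len(report["cells"]) == 28
    assert expert_aggregation_deviation(case, "as-given")["weight_sum"] == (
        pytest.approx(0.8162)
    )


# ------------------------------------------------------------- run_pipeline


def test_pipeline_from_aggregated_reproduces_case_study(case):
    res = run_pipeline(
        None,
        case.config,
        entry_stage="aggregated",
        aggregated=case.aggregated,
        alternative_ids=case.alternative_ids,
        attribute_ids=case.attribute_ids,
    )
    assert max_matrix_dev(res.weighted, case.weighted) < 5e-4
    assert res.ranking == case.ranking
    assert res.cumulative == pytest.approx(case.cumulative, abs=2e-4)


def test_pipeline_intermediates_are_self_consistent(case):
    """Recomputing any stage from the stored predecessor reproduces the
    stored stage exactly."""
    cfg = case.config
    res = run_pipeline(
        None, cfg, entry_stage="aggregated", aggregated=case.aggregated
    )
    assert normalize(res.aggregated, cfg.attribute_kinds) == res.normalized
    assert (
        weight_matrix(res.normalized, cfg.attribute_weights, cfg.q)
        == res.weighted
    )
    assert compute_baa(res.weighted, cfg.q) == res.baa
    assert distance_matrix(res.weighted, res.baa, cfg.q) == res.distances
    assert cumulative_scores(res.distances) == res.cumulative
    assert rank(res.cumulative, res.alternative_ids) == res.ranking


def test_pipeline_from_experts_runs_and_validates(case):
    res = run_pipeline(case.cube, case.config, entry_stage="experts")
    assert len(res.cumulative) == 7
    assert len(res.baa) == 4
    with pytest.raises(DomainError):
        run_pipeline(None, case.config, entry_stage="experts")
    with pytest.raises(DomainError):
        run_pipeline(case.cube, case.config, entry_stage="bogus")


def test_cumulative_invariant_under_attribute_permutation(case):
    cfg = case.config
    res = run_pipeline(None, cfg, entry_stage="aggregated",
                       aggregated=case.aggregated)
    perm = [3, 1, 0, 2]
    pcfg = PipelineConfig(
        q=cfg.q,
        scale=cfg.scale,
        expert_weights=cfg.expert_weights,
        attribute_weights=WeightVector(
            tuple(cfg.attribute_weights.weights[j] for j in perm)
        ),
        attribute_kinds=tuple(cfg.attribute_kinds[j] for j in perm),
    )
    pagg = [[row[j] for j in perm] for row in case.aggregated]
    pres = run_pipeline(None, pcfg, entry_stage="aggregated", aggregated=pagg)
    assert pres.cumulative == pytest.approx(res.cumulative, abs=1e-12)
    assert pres.ranking == res.ranking


def test_dominant_alternative_attains_maximal_cumulative_value(scale8):
    """In an all-benefit problem, an alternative whose entries dominate all
    others componentwise must rank first."""
    cube = generate_cube(GeneratorSpec(n_experts=1, n_alternatives=5,
                                       n_attributes=3, seed=7, max_width=1))
    top = TLIVqROFN.from_indices(7, 7, 0, 0, scale8)
    matrix = [list(row) for row in cube.entries[0]]
    matrix[2] = [top, top, top]
    cfg = PipelineConfig(
        q=6,
        scale=scale8,
        expert_weights=WeightVector((1.0,)),
        attribute_weights=WeightVector((0.4, 0.3, 0.3)),
        attribute_kinds=("benefit",) * 3,
    )
    res = run_pipeline(None, cfg, entry_stage="aggregated", aggregated=matrix)
    assert res.ranking[0] == "A3"
    assert max(res.cumulative) == res.cumulative[2]


# ------------------------------------------------------------------- sweeps


def test_sweep_single_q_matches_pipeline(case):
    res = run_pipeline(None, case.config, entry_stage="aggregated",
                       aggregated=case.aggregated,
                       alternative_ids=case.alternative_ids)
    records = sensitivity_sweep(
        case.config, [case.config.q], entry_stage="aggregated",
        aggregated=case.aggregated, alternative_ids=case.alternative_ids,
    )
    assert len(records) == 1
    assert records[0]["cumulative"] == pytest.approx(res.cumulative)
    assert tuple(records[0]["ranking"]) == res.ranking
    assert records[0]["top"] == "Γ6"


def test_sweep_runs_below_one_even_when_constraint_breaks(case):
    """Small rungs violate the rung constraint on data elicited at q=6; the
    sweep must still run (warn mode) and report per-q rankings."""
    records = sensitivity_sweep(
        case.config, [0.5, 2, 6], entry_stage="aggregated",
        aggregated=case.aggregated, alternative_ids=case.alternative_ids,
    )
    assert [r["q"] for r in records] == [0.5, 2, 6]
    for rec in records:
        total = sum(rec["cumulative"])
        # S sums over alternatives equal the grand sum of distances
        res = run_pipeline(
            None,
            PipelineConfig(
                q=rec["q"], scale=case.scale,
                expert_weights=case.config.expert_weights,
                attribute_weights=case.config.attribute_weights,
                attribute_kinds=case.config.attribute_kinds,
                validation_mode="warn",
            ),
            entry_stage="aggregated", aggregated=case.aggregated,
        )
        grand = sum(d for row in res.distances for d in row)
        assert total == pytest.approx(grand, abs=1e-12)
    assert records[2]["top"] == "Γ6"
    with pytest.raises(DomainError):
        sensitivity_sweep(case.config, [0.0], entry_stage="aggregated",
                          aggregated=case.aggregated)


# --------------------------------------------------------------- dimensions


def test_dimension_errors(case, scale8):
    with pytest.raises(DimensionError):
        weight_matrix(case.aggregated, (0.5, 0.5), 6)
    with pytest.raises(DimensionError):
        distance_matrix(case.weighted, case.baa[:2], 6)
    with pytest.raises(DimensionError):
        DecisionCube.build(
            [[[TLIVqROFN.from_indices(1, 2, 1, 2, scale8)],
              [TLIVqROFN.from_indices(1, 2, 1, 2, scale8)] * 2]]
        )
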