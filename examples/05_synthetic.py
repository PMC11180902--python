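"""Run the full group-decision pipeline on a synthetic random instance.

The generator draws constraint-satisfying judgements (rejection sampling on
the rung constraint), so the instance is valid under strict validation; the
pipeline then runs end to end from the expert matrices.
"""

from tlmabac import (
    GeneratorSpec,
    PipelineConfig,
    WeightVector,
    generate_cube,
    run_pipeline,
)
from tlmabac.linguistic import LinguisticScale

spec = GeneratorSpec(n_experts=3, n_alternatives=5, n_attributes=4, seed=2024)
cube = generate_cube(spec)
print("generated cube shape (experts, alternatives, attributes):", cube.shape)

cfg = PipelineConfig(
    q=spec.q,
    scale=LinguisticScale(spec.tau),
    expert_weights=WeightVector((0.5, 0.3, 0.2)),
    attribute_weights=WeightVector((0.3, 0.3, 0.2, 0.2)),
    attribute_kinds=("benefit", "benefit", "cost", "benefit"),
    validation_mode="strict",
)
result = run_pipeline(cube, cfg, entry_stage="experts")
print("cumulative values:", [round(s, 4) for s in result.cumulative])
print("ranking:", " > ".join(result.ranking))
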