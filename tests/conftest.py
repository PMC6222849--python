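"""Shared fixtures: planted synthetic benchmarks and scaled-down sweep
configurations used across the suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pvpred import pipeline, synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Eight planted g-gap dipeptides at gaps 0-2, enrichment 8.
PLANTED = [
    (0, "A", "C"), (0, "L", "K"), (0, "V", "I"),
    (1, "G", "W"), (1, "D", "E"), (1, "S", "T"),
    (2, "F", "M"), (2, "K", "R"),
]
PLANT_SEED = 11
PIPELINE_SEED = 1


def planted_spec(enrichment: float = 8.0, seed: int = PLANT_SEED) -> synth.SynthSpec:
    return synth.SynthSpec(
        planted=[synth.PlantedPair(g, a, b, enrichment) for g, a, b in PLANTED],
        seed=seed,
    )


def desk_config(fused_width: int | None = None, **overrides) -> pipeline.PipelineConfig:
    """Desk-scale sweep settings: reduced 3x3 grid, tune-once, subsampled
    prefixes. Problem sizes documented in docs/methods.md."""
    stage2_ks = None
    if fused_width is not None:
        stage2_ks = sorted(
            set(range(1, min(10, fused_width) + 1))
            | set(range(12, fused_width + 1, 4))
            | {fused_width}
        )
    kwargs = dict(
        g_values=list(range(10)),
        grid_c=[2.0**e for e in (-1, 3, 7)],
        grid_gamma=[2.0**e for e in (-7, -3, 1)],
        stage1_k_values=[1, 2, 3, 4, 5, 6, 8, 10, 14, 18, 22, 26, 30],
        stage2_k_values=stage2_ks,
        tune="once",
        seed=PIPELINE_SEED,
    )
    kwargs.update(overrides)
    return pipeline.PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def planted_dataset():
    """99 positives with planted signal vs 208 background negatives."""
    pos, neg = synth.generate(planted_spec())
    return pos + neg


@pytest.fixture(scope="session")
def two_step_run(planted_dataset):
    """Full two-step pipeline on the planted benchmark, plus a label-permuted
    control run through the identical protocol."""
    seqs = planted_dataset
    cfg = desk_config()
    s1 = pipeline.run_stage1(seqs, cfg)
    cfg = desk_config(fused_width=s1.fused_width)
    s2 = pipeline.run_stage2(seqs, s1, cfg)

    rng = np.random.default_rng(2)
    perm = rng.permutation(len(seqs))
    labels = np.array([s.label for s in seqs])[perm]
    permuted = [
        type(s)(id=s.id, residues=s.residues, label=int(l))
        for s, l in zip(seqs, labels)
    ]
    p1 = pipeline.run_stage1(permuted, desk_config())
    p2 = pipeline.run_stage2(
        permuted, p1, desk_config(fused_width=p1.fused_width)
    )
    return {"stage1": s1, "stage2": s2, "control_stage2": p2, "seqs": seqs}
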