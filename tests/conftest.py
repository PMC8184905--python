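"""Shared fixtures: small synthetic cohorts and prepared desk-scale runs."""

from __future__ import annotations

import pytest

from datprog.cohort import CohortSpec, generate_cohort, split_cohort
from datprog.ensemble import FeatureAssembler, desk_scale_config
from datprog.experiments import ExperimentConfig, PreparedCohort, prepare_cohort
from datprog.imaging import ExtractorSpec, ImagingExtractor
from datprog.motor import UpdrsExtractor


@pytest.fixture(scope="session")
def tiny_extractor_spec() -> ExtractorSpec:
    return ExtractorSpec(conv_filters=4, conv_kernel=(3, 3, 3), lstm_hidden=8,
                         output_width=8, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort with small volumes, for fast pipeline tests."""
    spec = CohortSpec(n_patients=40, seed=11, volume_shape=(12, 12, 8))
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_partitions(small_cohort):
    return split_cohort(small_cohort, (0.6, 0.2, 0.2), seed=5)


@pytest.fixture(scope="session")
def small_assembler(tiny_extractor_spec, small_partitions) -> FeatureAssembler:
    train, _, _ = small_partitions
    imaging = ImagingExtractor(tiny_extractor_spec)
    return FeatureAssembler(imaging, UpdrsExtractor(tiny_extractor_spec)).fit(train)


@pytest.fixture(scope="session")
def small_blocks(small_assembler, small_partitions):
    train, val, test = small_partitions
    return (
        small_assembler.blocks(train),
        small_assembler.blocks(val),
        small_assembler.blocks(test),
    )


@pytest.fixture(scope="session")
def default_preps() -> dict[int, tuple[ExperimentConfig, PreparedCohort]]:
    """Five full-default cohorts (n=198, stub backbones) prepared once per
    master seed; shared by the recovery and ablation-ordering checks."""
    out = {}
    for seed in range(5):
        cfg = ExperimentConfig(master_seed=seed, training=desk_scale_config())
        out[seed] = (cfg, prepare_cohort(cfg))
    return out
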