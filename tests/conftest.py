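import pytest

import scramblescan as ss


@pytest.fixture(scope="session")
def small_dataset() -> ss.SyntheticDataset:
    """Forty loci at the default study conditions, exercising every
    category (scrambled, nonscrambled, multi-scaffold, alt-processed) plus
    somatic contaminants and introns."""
    cfg = ss.SimulationConfig(
        n_loci=40,
        rng_seed=11,
        alt_processing_prob=0.3,
        multi_scaffold_prob=0.2,
        intron_prob=0.3,
        n_somatic_contaminants=6,
    )
    return ss.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset) -> ss.PipelineResult:
    return ss.run_pipeline(
        ss.PipelineConfig(),
        small_dataset.scaffolds,
        small_dataset.transcripts,
        truth=small_dataset.truth,
        families=small_dataset.family_truth,
    )
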