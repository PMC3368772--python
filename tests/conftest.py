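import random

import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from mirforge.pipeline import PipelineConfig, run_pipeline
from mirforge.simulate import EditingSpec, SyntheticConfig, generate_study


def planted_study_config(seed: int = 42) -> SyntheticConfig:
    """The deterministic planted-truth study: 20 rule-satisfying hairpins,
    20 single-rule decoys, 48 families (12 above 1,000 reads), editing and
    -1+UU isoforms at fixed rates, background noise off."""
    return SyntheticConfig(
        seed=seed,
        editing={
            2: EditingSpec(position=9, rate=1 / 13),
            5: EditingSpec(position=4, rate=0.05),
        },
        minus1_uu={3: 0.02, 7: 0.01},
        n_background_unique=0,
    )


@pytest.fixture(scope="session")
def planted_study():
    cfg = planted_study_config()
    reads, transcripts, mature_db, references, truth = generate_study(cfg)
    return cfg, reads, transcripts, mature_db, references, truth


@pytest.fixture(scope="session")
def planted_result(planted_study):
    cfg, reads, transcripts, mature_db, references, truth = planted_study
    result = run_pipeline(
        reads, transcripts, mature_db, references, PipelineConfig(adapter=cfg.adapter)
    )
    return result, truth


@pytest.fixture()
def rng():
    return random.Random(20240901)
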