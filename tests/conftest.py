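import numpy as np
import pytest

from priormae import fixtures, occurrence


@pytest.fixture(scope="session")
def tiny_config():
    return fixtures.SyntheticStudyConfig(
        grid_shape=(16, 16, 16), n_regions=4, n_cases=30, noise_sd=0.1, seed=11
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return fixtures.make_atlas(tiny_config)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    atlas, rates, labels, intensity = fixtures.make_study(tiny_config)
    return {"atlas": atlas, "rates": rates, "labels": labels,
            "intensity": intensity}


@pytest.fixture(scope="session")
def tiny_weight_map(tiny_study):
    counts = occurrence.accumulate_occurrence(tiny_study["labels"])
    table = occurrence.region_probability(counts, tiny_study["atlas"])
    return occurrence.build_weight_map(table, tiny_study["atlas"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
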