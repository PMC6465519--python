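import pytest

from st1t2 import GeneratorConfig
from st1t2.synthetic import generate_subject_table

# Small grid with the same 128 mm physical field of view as the 64^3 / 2 mm
# default, so the configured lesion loads remain feasible.
SMALL_GRID = {"grid_shape": (32, 32, 32), "voxel_size_mm": 4.0}


@pytest.fixture
def small_config():
    """Factory for a small, fast cohort configuration."""

    def make(**overrides):
        kw = dict(SMALL_GRID, n_per_group=4, female_count=2, seed=1234)
        kw.update(overrides)
        return GeneratorConfig(**kw)

    return make


@pytest.fixture
def noiseless_config(small_config):
    """Factory with gains, noise and bias field all disabled."""

    def make(**overrides):
        kw = dict(gain_sd_t1w=0.0, gain_sd_t2w=0.0, noise_sd=0.0, bias_amplitude=0.0)
        kw.update(overrides)
        return small_config(**kw)

    return make


def first_record(config, group="MS"):
    table = generate_subject_table(config)
    return table[table["group"] == group].iloc[0].to_dict()
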