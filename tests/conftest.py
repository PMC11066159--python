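import pytest

from wobblescan import synthetic_data


@pytest.fixture(scope="session")
def dataset():
    """The packaged 15-anticodon reference dataset."""
    return synthetic_data.reference_dataset()


@pytest.fixture(scope="session")
def reference_re_table(dataset):
    """Aggregated RE table flattened from the reference dataset."""
    return synthetic_data.reference_re_table(dataset)


@pytest.fixture
def clean_trace():
    """A noise-free, unquantized synthetic trace with a lone mixed T/C
    position, plus its generating spec."""

    def make(fraction: float, seed: int = 0, **overrides):
        sequence = "GGATCACAGGTATTCGACTGCA"  # index 10 is the mixed T
        mixed = {}
        if fraction > 0:
            mixed[10] = {"C": fraction, "T": 1.0 - fraction}
        spec = synthetic_data.SyntheticTraceSpec(
            sequence=sequence,
            mixed_positions=mixed,
            noise_sd=0.0,
            quantize=False,
            seed=seed,
            **overrides,
        )
        return synthetic_data.simulate_trace(spec), spec

    return make
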