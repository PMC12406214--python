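import numpy as np
import pytest
from dataclasses import replace

from tailbench.simulate import rna002_config, simulate_dataset


@pytest.fixture(scope="session")
def rna002():
    return rna002_config()


@pytest.fixture(scope="session")
def tiny_config():
    """Small-read config (reads ~200-260 samples) for oracle-scale tests."""
    return replace(
        rna002_config(),
        rate_mean=2.5, rate_sd=0.3,
        adapter_samples_mean=50, adapter_samples_sd=5,
        transcript_len_nt=25,
        tail_population=[(10.0, 1.0), (20.0, 1.0), (25.0, 1.0)],
    )


@pytest.fixture(scope="session")
def clean_dataset_60(rna002):
    """Artifact-free reads with a known 60 nt tail."""
    cfg = replace(rna002, tail_population=[(60.0, 1.0)])
    return cfg, simulate_dataset(cfg, 200, seed=1206)


def binom99(n: int, p: float) -> tuple[int, int]:
    """Exact binomial central 99% interval on the count scale."""
    from scipy.stats import binom
    return int(binom.ppf(0.005, n, p)), int(binom.isf(0.005, n, p))
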