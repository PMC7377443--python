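import numpy as np
import pytest
from hypothesis import settings

from orfselect.core import default_context
from orfselect.simulate import SyntheticConfig, make_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

STOPS = {"TAA", "TAG", "TGA"}


def naive_stop_scan(seq: str, frame_offset: int = 0) -> list[int]:
    """Independent brute-force per-codon stop scanner (test oracle)."""
    out = []
    k = 0
    for i in range(frame_offset, len(seq) - 2, 3):
        if seq[i : i + 3] in STOPS:
            out.append(k)
        k += 1
    return out


@pytest.fixture(scope="session")
def ctx():
    return default_context()


@pytest.fixture(scope="session")
def small_dataset(ctx):
    """A small error-free synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_genes=5,
        gene_length_range=(450, 900),
        n_fragments=300,
        substitution_rate=0.0,
        adapter_indel_rate=0.0,
        seed=7,
    )
    return make_dataset(cfg, ctx)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
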