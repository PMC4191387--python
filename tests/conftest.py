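import pytest

from snvprofiler.catalogs import ProteinRecord
from snvprofiler.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic data set shared by read-only tests."""
    cfg = SynthConfig(
        seed=11, n_proteins=8, mean_length=120, n_variants=600, n_samples=5
    )
    return generate_bundle(cfg)


@pytest.fixture
def toy_proteome():
    return [
        ProteinRecord("P1", "MKTAYIAKQRNASTVLKQSE", gene="G1"),
        ProteinRecord("P2", "ANATQRSTWCELKNGSAMKR", gene="G2"),
        ProteinRecord("P3", "GGSSLLKKRRNNPPTTYYCC", gene="G3"),
    ]
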