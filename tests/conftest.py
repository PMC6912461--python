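import pytest

from fourc_rdna.synthetic_data import SyntheticConfig, write_fixture


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    """Default synthetic two-replicate/two-condition study, on disk."""
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(outdir, SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def hc_fixture(tmp_path_factory):
    """High-concordance variant (no replicate-specific contacts) for QC."""
    outdir = tmp_path_factory.mktemp("fixture_hc")
    return write_fixture(outdir, SyntheticConfig(seed=11).high_concordance())
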