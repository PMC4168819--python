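import pytest

from homdel.synthetic_data import make_canonical_model, write_fixture


@pytest.fixture(scope="session")
def canonical():
    """Canonical toy genome + 7-exon transcript model (seed fixed)."""
    genome, model, _ = make_canonical_model(seed=1)
    return genome, model


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic input directory for pipeline-level tests."""
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(out, seed=1)
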