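import pytest

from herbnet import PrescriptionCorpus


@pytest.fixture
def uniform_corpus() -> PrescriptionCorpus:
    """One representative prescription of 4 distinct herbs, plus background."""
    prescriptions = {
        "rep": ["a", "b", "c", "d"],
        "bg1": ["a", "e"],
        "bg2": ["e", "f"],
    }
    return PrescriptionCorpus(prescriptions=prescriptions, representative_ids=["rep"])


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """Full synthetic demo dataset (all pipeline inputs plus truth files)."""
    from herbnet import generate_all

    out = tmp_path_factory.mktemp("demo")
    paths = generate_all(seed=1, out_dir=out)
    return out, paths
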