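import pytest

from cubkit.datasets import pcv_rscu_profiles, sus_scrofa_reference


@pytest.fixture(scope="session")
def pcv_profiles():
    """Bundled RSCU profiles: PCV1..PCV4 + Sus_scrofa."""
    return pcv_rscu_profiles()


@pytest.fixture(scope="session")
def host_reference():
    """Sus scrofa usage as a ReferenceUsageTable (rscu units)."""
    return sus_scrofa_reference()


@pytest.fixture()
def fasta_file(tmp_path):
    """Write records to a FASTA file, return its path."""

    def _make(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _make
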