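import pytest

from cleavekit.digestion import ProteinRecord, get_enzyme


@pytest.fixture
def proalanase():
    return get_enzyme("proalanase", max_missed=0, min_len=1, max_len=50)


@pytest.fixture
def trypsin_p():
    return get_enzyme("trypsin_p", max_missed=0, min_len=1, max_len=50)


@pytest.fixture
def toy_record():
    return ProteinRecord(id="toy", sequence="AAPKGPR")


@pytest.fixture
def write_fasta(tmp_path):
    """Write header/sequence pairs to a temporary FASTA file."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        lines = []
        for header, seq in entries:
            lines.append(f">{header}")
            lines.append(seq)
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
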