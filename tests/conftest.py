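import pytest

from galphase import DisorderTrack, ProteinRecord


@pytest.fixture
def write_fasta_text(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def record_with_track():
    """A 60-residue record fully disordered at score 1.0."""
    record = ProteinRecord(id="rec1", sequence="G" * 60)
    track = DisorderTrack(record_id="rec1", scores=(1.0,) * 60)
    return record, track
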