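import numpy as np
import pytest

from mosaicmeth.genome_io import SequenceRecord


@pytest.fixture
def write_fasta(tmp_path):
    """Write records to a temporary FASTA file and return its path."""

    def _write(records: dict[str, str], name: str = "test.fa", width: int = 60):
        path = tmp_path / name
        with open(path, "wt") as fh:
            for rec_name, seq in records.items():
                fh.write(f">{rec_name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    return _write


@pytest.fixture
def random_sequence():
    """A seeded random DNA sequence factory."""

    def _make(length: int, seed: int = 0, alphabet: str = "ACGT", name: str = "chr1"):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(alphabet), size=length))
        return SequenceRecord(name=name, sequence=seq)

    return _make
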