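import numpy as np
import pytest

from ssrscan import generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def small_panel():
    """A small deterministic panel shared by integration tests."""
    return generate_panel(
        n_genomes=3, genome_length=100_000, window_size=10_000, seed=42
    )
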