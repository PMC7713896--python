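import gzip

import numpy as np
import pytest

from sketch2phylo import GenomeRecord, EvoModelParams, evolve_pair


@pytest.fixture
def write_fasta(tmp_path):
    """Factory writing a FASTA (optionally gzipped) file and returning its path."""

    def _write(text: str, name: str = "genome.fasta", gz: bool = False):
        path = tmp_path / name
        if gz:
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)
        return path

    return _write


@pytest.fixture
def genome_pair_factory():
    """Simulated genome pairs at a given divergence, as GenomeRecord objects."""

    def _make(d: float, length: int, seed: int, **model_kwargs):
        model = EvoModelParams(**model_kwargs)
        pair = evolve_pair(d, model, length, seed=seed)
        return (
            GenomeRecord.from_sequence(f"x{seed}", pair.seq_x),
            GenomeRecord.from_sequence(f"y{seed}", pair.seq_y),
            pair,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
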