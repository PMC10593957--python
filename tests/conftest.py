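import numpy as np
import pytest

from tinpatneo.config import SimulationConfig
from tinpatneo.simulate import generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=150_000,
        n_te=40,
        n_ref_transcripts=14,
        n_novel_transcripts=30,
        n_induced=10,
        n_planted_peptides=4,
        n_background_peptides=30,
        n_canonical_proteins=20,
    )


@pytest.fixture(scope="session")
def dataset(small_config):
    return generate_dataset(small_config)


def random_transcript(rng, chrom="chr1", lo=0, hi=3000, max_exons=4, tid="q"):
    """A random valid transcript for oracle-equivalence tests."""
    from tinpatneo.models import TranscriptModel

    k = int(rng.integers(1, max_exons + 1))
    exon_lens = rng.integers(10, 80, size=k)
    intron_lens = rng.integers(5, 120, size=max(0, k - 1))
    total = int(exon_lens.sum() + intron_lens.sum())
    start = int(rng.integers(lo, max(lo + 1, hi - total)))
    exons, pos = [], start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < k - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, tuple(exons))
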