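import numpy as np
import pytest

from te_insite.genomic_core import AlignmentRecord, Genome, GenomicInterval


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_genome(rng: np.random.Generator, lengths: dict) -> Genome:
    return Genome({name: random_sequence(rng, n) for name, n in lengths.items()})


def random_records(rng: np.random.Generator, genome: Genome, n: int,
                   read_length: int = 50, samples=("s1",)) -> list:
    records = []
    names = genome.names
    for _ in range(n):
        chrom = names[rng.integers(0, len(names))]
        limit = genome.length(chrom) - read_length
        start = int(rng.integers(0, max(1, limit)))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(AlignmentRecord(
            GenomicInterval(chrom, start, start + read_length, strand),
            mapq=int(rng.choice([0, 30, 255])),
            sample=samples[rng.integers(0, len(samples))]))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    return random_genome(rng, {"chr1": 2000, "chr2": 1500, "chrM": 400})
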