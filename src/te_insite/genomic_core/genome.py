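"""Reference genome container and alignment-record transforms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .intervals import GenomicInterval

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


@dataclass
class Genome:
    """Named nucleotide sequences defining the coordinate frame.

    ``mito_name`` flags a contig excluded from library-size normalization.
    """

    sequences: Dict[str, str]
    mito_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one sequence")
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has empty sequence")
        if self.mito_name is not None and self.mito_name not in self.sequences:
            raise ValueError(f"mito contig {self.mito_name!r} not in genome")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> List[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        try:
            return len(self.sequences[chrom])
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.sequences:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.length(interval.chrom):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends beyond chromosome end ({self.length(interval.chrom)})"
            )

    def fetch(self, interval: GenomicInterval) -> str:
        self.validate_interval(interval)
        return self.sequences[interval.chrom][interval.start:interval.end]


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """One aligned read or fragment; the unit counted everywhere."""

    interval: GenomicInterval
    mapq: int = 0
    sample: str = "sample"
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass
class InsertionSet:
    """Transposon insertion sites, each tagged with a TE family."""

    insertions: List[Tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for family, iv in self.insertions:
            if not family:
                raise ValueError(f"insertion {iv} has empty family name")

    @property
    def families(self) -> Set[str]:
        return {family for family, _ in self.insertions}

    def __len__(self) -> int:
        return len(self.insertions)

    def __iter__(self):
        return iter(self.insertions)

    def subset(self, families: Iterable[str]) -> "InsertionSet":
        wanted = set(families)
        return InsertionSet([(f, iv) for f, iv in self.insertions if f in wanted])

    def reference_points(self) -> List[Tuple[str, str, int, str]]:
        """(family, chrom, center, strand) per insertion."""
        return [(f, iv.chrom, iv.center, iv.strand) for f, iv in self.insertions]


def deduplicate(records: Sequence[AlignmentRecord]) -> List[AlignmentRecord]:
    """Remove PCR duplicates.

    Records sharing (chrom, start, end, strand, sample) collapse to one
    survivor (the highest-mapq representative). The key includes the sample
    so replicate libraries never deduplicate against each other. Output is
    sorted by coordinates then mapq descending, making the result
    independent of input order.
    """
    best: Dict[tuple, AlignmentRecord] = {}
    for rec in records:
        iv = rec.interval
        key = (iv.chrom, iv.start, iv.end, iv.strand, rec.sample)
        kept = best.get(key)
        if kept is None or rec.mapq > kept.mapq:
            best[key] = rec
    # keys are unique, so sorting items orders purely by coordinates/sample
    return [rec for _, rec in sorted(best.items())]


def fragment_transform(
    record: AlignmentRecord,
    fragment_length: int,
    center: bool,
    genome: Genome,
) -> GenomicInterval:
    """Extend a read to the expected fragment and optionally re-center it.

    The read is extended in its 3' direction to ``fragment_length``
    (clipped at chromosome bounds). With ``center``, an interval of the
    original read length is placed at the extended fragment's midpoint.
    The result never leaves the chromosome and never exceeds
    ``fragment_length`` in width.
    """
    iv = record.interval
    read_len = iv.width
    if fragment_length < read_len:
        raise ValueError(
            f"fragment_length {fragment_length} < read length {read_len}"
        )
    chrom_len = genome.length(iv.chrom)
    if iv.strand == "-":
        frag_start, frag_end = iv.end - fragment_length, iv.end
    else:
        frag_start, frag_end = iv.start, iv.start + fragment_length
    frag_start = max(0, frag_start)
    frag_end = min(chrom_len, frag_end)
    if not center:
        return GenomicInterval(iv.chrom, frag_start, frag_end, iv.strand)
    midpoint = (frag_start + frag_end) // 2
    start = max(0, midpoint - read_len // 2)
    end = min(chrom_len, start + read_len)
    start = max(0, min(start, end - 1))
    return GenomicInterval(iv.chrom, start, end, iv.strand)
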