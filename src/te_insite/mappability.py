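"""Per-base genome mappability from exhaustive k-mer self-matching.

A k-mer starting at position p is *uniquely mapping* iff its sequence
occurs at exactly one location over both strands of the whole genome (its
own origin). Mappability at a base x is the number of uniquely mapping
k-mers covering x, divided by the k-mer length, so each unique k-mer
contributes a total mass of 1 and the track sums to the number of unique
k-mers exactly.

Uniqueness is exact string matching over both strands; a mismatch-tolerant
aligner can be substituted via the ``unique_flags`` hook of
:func:`kmer_mappability`. A palindromic k-mer whose two strand hits share a
locus counts as unique. Windows containing symbols other than A/C/G/T are
treated as unmappable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genomic_core.genome import Genome
from .genomic_core.intervals import GenomicInterval

_COMP_TABLE = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


@dataclass
class MappabilityTrack:
    """Per-chromosome per-base uniqueness fractions in [0, 1]."""

    values: Dict[str, np.ndarray]
    kmer_length: int

    def __post_init__(self) -> None:
        for chrom, vec in self.values.items():
            self.values[chrom] = np.asarray(vec, dtype=float)

    def total_mass(self) -> float:
        return float(sum(vec.sum() for vec in self.values.values()))

    def chrom(self, name: str) -> np.ndarray:
        return self.values[name]


def _chrom_bytes(genome: Genome) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """(forward, reverse-complement) uint8 views of each chromosome."""
    out = {}
    for name, seq in genome.sequences.items():
        fwd = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        rc = np.frombuffer(seq.upper().encode().translate(_COMP_TABLE)[::-1],
                           dtype=np.uint8)
        out[name] = (fwd, rc)
    return out


_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE_TABLE[_b] = _i


def _valid_windows(codes: np.ndarray, n: int) -> np.ndarray:
    """True for windows made purely of A/C/G/T."""
    m = len(codes) - n + 1
    if m <= 0:
        return np.zeros(0, dtype=bool)
    bad = np.concatenate([[0], np.cumsum(codes == 255)])
    return (bad[n:] - bad[:-n]) == 0


def _pack_windows(codes: np.ndarray, n: int) -> np.ndarray:
    """2-bit-pack every length-n window into ceil(n/32) uint64 words.

    Exact (no hashing): two windows are equal iff their packed rows are.
    """
    m = len(codes) - n + 1
    n_words = (n + 31) // 32
    if m <= 0:
        return np.empty((0, n_words), dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    words = np.empty((m, n_words), dtype=np.uint64)
    for w in range(n_words):
        lo, hi = 32 * w, min(32 * w + 32, n)
        acc = np.zeros(m, dtype=np.uint64)
        for i in range(lo, hi):
            acc = (acc << np.uint64(2)) | codes64[i:i + m]
        words[:, w] = acc
    return words


def _row_multiset_counts(blocks: List[np.ndarray]) -> List[np.ndarray]:
    """Occurrence count of each row across the concatenated row multiset.

    Rows are uint64 word vectors; counting sorts them lexicographically and
    run-length-encodes the result.
    """
    sizes = [len(b) for b in blocks]
    nonempty = [b for b in blocks if len(b)]
    if not nonempty:
        return [np.empty(0, dtype=np.int64) for _ in blocks]
    stacked = np.concatenate(nonempty, axis=0)
    order = np.lexsort(stacked.T[::-1])
    ranked = stacked[order]
    boundary = np.empty(len(ranked), dtype=bool)
    boundary[0] = True
    np.any(ranked[1:] != ranked[:-1], axis=1, out=boundary[1:])
    group = np.cumsum(boundary) - 1
    group_counts = np.bincount(group)
    per_row = np.empty(len(stacked), dtype=np.int64)
    per_row[order] = group_counts[group]
    out, offset = [], 0
    for size in sizes:
        out.append(per_row[offset:offset + size])
        offset += size
    return out


def _coverage_from_unique(length: int, unique_mask: np.ndarray, n: int,
                          mass: float) -> np.ndarray:
    """Accumulate per-base coverage: each unique k-mer adds `mass` over n bp."""
    diff = np.zeros(length + 1)
    starts = np.flatnonzero(unique_mask)
    np.add.at(diff, starts, mass)
    np.add.at(diff, starts + n, -mass)
    return np.maximum(np.cumsum(diff)[:length], 0.0)  # clip cumsum noise


def kmer_mappability(
    genome: Genome,
    n: int,
    unique_flags: Optional[Dict[str, np.ndarray]] = None,
) -> MappabilityTrack:
    """Exhaustive n-mer mappability track.

    ``unique_flags`` (per-chromosome boolean vectors over k-mer start
    positions) substitutes an external aligner's unique/multi calls for the
    built-in exact-match criterion.
    """
    if n < 1:
        raise ValueError("k-mer length n must be >= 1")
    chroms = _chrom_bytes(genome)
    names = list(genome.sequences)

    if unique_flags is None:
        packed, valid = {}, {}
        blocks = []
        for name in names:
            for strand in (0, 1):
                codes = _CODE_TABLE[chroms[name][strand]]
                ok = _valid_windows(codes, n)
                rows = _pack_windows(np.minimum(codes, 3), n)
                packed[(name, strand)] = rows
                valid[(name, strand)] = ok
                blocks.append(rows[ok])  # windows with non-ACGT bases never map
        counts = _row_multiset_counts(blocks)
        unique_flags = {}
        for i, name in enumerate(names):
            fwd_rows = packed[(name, 0)]
            ok = valid[(name, 0)]
            cc = np.zeros(len(fwd_rows), dtype=np.int64)
            cc[ok] = counts[2 * i]
            if len(fwd_rows) == 0:
                unique_flags[name] = np.zeros(0, dtype=bool)
                continue
            # rc rows reversed row-wise align the revcomp of each fwd window
            palindromic = (fwd_rows == packed[(name, 1)][::-1]).all(axis=1)
            unique_flags[name] = (cc == 1) | ((cc == 2) & palindromic)

    values = {}
    for name in names:
        length = genome.length(name)
        mask = np.asarray(unique_flags.get(name, np.zeros(0, dtype=bool)), dtype=bool)
        values[name] = _coverage_from_unique(length, mask, n, 1.0 / n)
    return MappabilityTrack(values, kmer_length=n)


def paired_mappability(genome: Genome, n: int, shift: int) -> MappabilityTrack:
    """Paired-fragment mappability approximation for 2 x n bp read pairs.

    Averages two tracks position-wise: (i) single-fragment mappability with
    k-mer length 2n, and (ii) a pair track where mate 1 is the n-mer at p
    and mate 2 the reverse complement of the n-mer at p + shift; the pair is
    unique iff that ordered pair of sequences with that separation occurs at
    one genomic locus over both strands. Each unique pair deposits 1/(2n)
    over both mate spans (total mass 1). Pairs whose second mate would run
    off the chromosome are skipped.
    """
    if n < 1:
        raise ValueError("k-mer length n must be >= 1")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    single = kmer_mappability(genome, 2 * n)

    chroms = _chrom_bytes(genome)
    names = list(genome.sequences)
    n_words = (n + 31) // 32
    pair_blocks: List[np.ndarray] = []
    swapped_blocks: List[np.ndarray] = []
    pair_valid: List[np.ndarray] = []
    for name in names:
        fwd, rc = chroms[name]
        length = len(fwd)
        n_pairs = length - (shift + n) + 1  # start positions 0 .. length-shift-n
        if n_pairs <= 0:
            pair_blocks.append(np.empty((0, 2 * n_words), dtype=np.uint64))
            swapped_blocks.append(np.empty((0, 2 * n_words), dtype=np.uint64))
            pair_valid.append(np.zeros(0, dtype=bool))
            continue
        codes_f = _CODE_TABLE[fwd]
        codes_r = _CODE_TABLE[rc]
        wins = _pack_windows(np.minimum(codes_f, 3), n)
        ok_f = _valid_windows(codes_f, n)
        mate1 = wins[:n_pairs]
        # revcomp of the n-mer at p+shift, built from the rc strand windows
        rc_wins = _pack_windows(np.minimum(codes_r, 3), n)[::-1]
        ok_r = _valid_windows(codes_r, n)[::-1]
        mate2 = rc_wins[shift:shift + n_pairs]
        pair_blocks.append(np.concatenate([mate1, mate2], axis=1))
        swapped_blocks.append(np.concatenate([mate2, mate1], axis=1))
        pair_valid.append(ok_f[:n_pairs] & ok_r[shift:shift + n_pairs])

    blocks = [rows[ok] for rows, ok in zip(pair_blocks + swapped_blocks,
                                           pair_valid + pair_valid)]
    counts = _row_multiset_counts(blocks)
    pair_values = {}
    for i, name in enumerate(names):
        length = genome.length(name)
        rows = pair_blocks[i]
        vec = np.zeros(length)
        if len(rows):
            cc = np.zeros(len(rows), dtype=np.int64)
            cc[pair_valid[i]] = counts[i]
            palindromic = (rows == swapped_blocks[i]).all(axis=1)
            unique = (cc == 1) | ((cc == 2) & palindromic)
            vec += _coverage_from_unique(length, unique, n, 1.0 / (2 * n))
            diff = np.zeros(length + 1)
            starts = np.flatnonzero(unique) + shift
            np.add.at(diff, starts, 1.0 / (2 * n))
            np.add.at(diff, starts + n, -1.0 / (2 * n))
            vec += np.cumsum(diff)[:length]
        pair_values[name] = np.maximum(vec, 0.0)

    values = {name: (single.values[name] + pair_values[name]) / 2.0
              for name in names}
    return MappabilityTrack(values, kmer_length=n)


def region_mean_mappability(track: MappabilityTrack,
                            interval: GenomicInterval) -> float:
    """Arithmetic mean of per-base mappability over an interval."""
    if interval.chrom not in track.values:
        raise ValueError(f"unknown chromosome {interval.chrom!r} in track")
    vec = track.values[interval.chrom]
    if interval.end > len(vec):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "extends beyond the track")
    if interval.width == 0:
        raise ValueError("zero-width interval")
    return float(vec[interval.start:interval.end].mean())
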