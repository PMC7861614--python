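"""Readers and writers for every on-disk format the pipeline touches.

Interchange formats are deliberately plain text: FASTA for sequences,
BED4/BED6 for insertions and regions, TSV tables (with headers) for genes,
alignments and all results, bedGraph for per-base tracks. A SAM dialect is
accepted as an alternative alignment input.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .genome import AlignmentRecord, Genome, InsertionSet
from .intervals import GenomicInterval

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
ALIGNMENT_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "sample"]


class InputError(IOError):
    """A required input file is missing or unreadable."""


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    return path


def sigfmt(value: float, digits: int = 6) -> str:
    """Render a float with a fixed number of significant digits.

    Result tables never carry floating noise; all float output funnels
    through here.
    """
    if value != value:  # NaN
        return "NA"
    return f"{value:.{digits}g}"


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(_require(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(path: str, sequences: Dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_genome(path: str, mito_name: Optional[str] = None) -> Genome:
    seqs = read_fasta(path)
    if mito_name is not None and mito_name not in seqs:
        mito_name = None
    return Genome(seqs, mito_name=mito_name)


# --------------------------------------------------------------------------
# BED (0-based half-open; column 4 = name/family, column 6 = strand)

def read_bed(path: str, genome: Optional[Genome] = None) -> List[Tuple[str, GenomicInterval]]:
    entries: List[Tuple[str, GenomicInterval]] = []
    with open(_require(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED line needs >= 4 columns (name = family)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                if genome is not None:
                    genome.validate_interval(iv)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            entries.append((name, iv))
    return entries


def write_bed(path: str, entries: Iterable[Tuple[str, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for name, iv in entries:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_insertions(path: str, genome: Optional[Genome] = None) -> InsertionSet:
    return InsertionSet(read_bed(path, genome))


def write_insertions(path: str, insertions: InsertionSet) -> None:
    write_bed(path, insertions.insertions)


# --------------------------------------------------------------------------
# Gene table (TSV: gene_id, chrom, tss, strand; TSS 0-based)

def read_gene_table(path: str, genome: Optional[Genome] = None) -> pd.DataFrame:
    table = pd.read_csv(_require(path), sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if genome is not None:
        for row in table.itertuples():
            if row.chrom not in genome.sequences:
                raise ValueError(f"{path}: unknown chromosome {row.chrom!r}")
            if not 0 <= row.tss < genome.length(row.chrom):
                raise ValueError(
                    f"{path}: TSS {row.tss} outside chromosome {row.chrom}")
    return table[GENE_TABLE_COLUMNS + [c for c in table.columns if c not in GENE_TABLE_COLUMNS]]


def write_gene_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Alignment table (native TSV interchange format)

def read_alignments(path: str, genome: Optional[Genome] = None) -> List[AlignmentRecord]:
    table = pd.read_csv(_require(path), sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(ALIGNMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: alignment table missing columns {sorted(missing)}")
    records: List[AlignmentRecord] = []
    for idx, row in enumerate(table.itertuples(), start=2):
        try:
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            if genome is not None:
                genome.validate_interval(iv)
            records.append(AlignmentRecord(iv, mapq=int(row.mapq), sample=row.sample))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from exc
    return records


def write_alignments(path: str, records: Sequence[AlignmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{rec.mapq}\t{rec.sample}\n")


def read_sam(path: str, sample: Optional[str] = None) -> List[AlignmentRecord]:
    """Read a text SAM file (FLAG bit 0x10 for strand, MAPQ column).

    Sample defaults to the file basename without extension.
    """
    import pysam

    if sample is None:
        sample = os.path.splitext(os.path.basename(path))[0]
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(_require(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(aln.reference_name, aln.reference_start,
                                 aln.reference_end, strand)
            records.append(AlignmentRecord(
                iv, mapq=aln.mapping_quality, sample=sample,
                is_duplicate=aln.is_duplicate))
    return records


def read_alignments_any(path: str, genome: Optional[Genome] = None,
                        sample: Optional[str] = None) -> List[AlignmentRecord]:
    if path.endswith(".sam"):
        return read_sam(path, sample=sample)
    return read_alignments(path, genome)


# --------------------------------------------------------------------------
# bedGraph

def write_bedgraph(path: str, per_chrom_values, digits: int = 4) -> None:
    """Write per-base vectors as a run-length-merged bedGraph track."""
    with open(path, "w") as fh:
        for chrom in per_chrom_values:
            values = per_chrom_values[chrom]
            run_start = 0
            prev = None
            for pos, value in enumerate(values):
                text = sigfmt(float(value), digits)
                if text != prev:
                    if prev is not None and prev != "0":
                        fh.write(f"{chrom}\t{run_start}\t{pos}\t{prev}\n")
                    run_start, prev = pos, text
            if prev is not None and prev != "0":
                fh.write(f"{chrom}\t{run_start}\t{len(values)}\t{prev}\n")


def read_bedgraph(path: str, lengths: Dict[str, int]):
    """Read a bedGraph back into dense per-base float vectors."""
    import numpy as np

    tracks = {chrom: np.zeros(length) for chrom, length in lengths.items()}
    with open(_require(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            tracks[chrom][int(start):int(end)] = float(value)
    return tracks


# --------------------------------------------------------------------------
# Bundle loader

def load_inputs(paths: Dict[str, str], config: PipelineConfig,
                mito_name: Optional[str] = None):
    """Load genome, insertions, gene table and alignments in one call.

    ``paths`` keys: genome, insertions, genes, alignments (a path or a list
    of paths; ``.sam`` files are parsed as SAM).
    """
    genome = read_genome(paths["genome"], mito_name=mito_name)
    insertions = read_insertions(paths["insertions"], genome)
    genes = read_gene_table(paths["genes"], genome)
    aln_paths = paths["alignments"]
    if isinstance(aln_paths, (str, os.PathLike)):
        aln_paths = [aln_paths]
    records: List[AlignmentRecord] = []
    for p in aln_paths:
        records.extend(read_alignments_any(str(p), genome))
    return genome, insertions, genes, records
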