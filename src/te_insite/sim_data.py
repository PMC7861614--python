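"""Synthetic genomes, insertions, ChIP fragments and RNA-seq counts.

Every pipeline stage is testable at desk scale against planted truth: a
small multi-chromosome genome (plus a mitochondrial contig) carrying
diverged TE-consensus copies, chromatin enrichment domains around
insertions that are depleted (or gained, for an active mark) in knockdown
samples, and negative-binomial counts for genes and TE families with
planted de-repression and secondary upregulation of insertion-proximal
genes. All randomness flows from one root seed through per-component
spawned streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genomic_core.config import (DEFAULT_OTHER_FAMILIES,
                                  DEFAULT_UPREGULATED_FAMILIES, PipelineConfig)
from .genomic_core.genome import AlignmentRecord, Genome, InsertionSet
from .genomic_core.intervals import GenomicInterval
from .genomic_core import io as gio

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the synthetic dataset."""

    n_chrom: int = 3
    chrom_length: int = 500_000
    mito_length: int = 20_000
    mito_name: str = "chrM"
    families: List[str] = field(default_factory=lambda: (
        list(DEFAULT_UPREGULATED_FAMILIES) + list(DEFAULT_OTHER_FAMILIES) + ["roo"]))
    te_length_range: Tuple[int, int] = (800, 3000)
    insertions_per_family: Union[int, Dict[str, int]] = 2
    divergence: float = 0.05
    n_genes: int = 200
    tss_near_fraction: float = 0.3
    het_region_length: int = 100_000
    # chromatin model
    enrichment_factor: float = 8.0
    depletion_factor: float = 4.0
    domain_width: int = 10_000
    upregulated_domain_width: Optional[int] = None  # defaults to domain_width
    active_mark_baseline: float = 1.0
    read_length: int = 50
    fragment_length: int = 260
    multimapper_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    # expression model
    te_lfc: float = 3.0
    gene_secondary_lfc: float = 1.5
    gene_length: int = 2000
    seed: int = 0

    def insertion_count(self, family: str) -> int:
        if isinstance(self.insertions_per_family, dict):
            return int(self.insertions_per_family.get(family, 0))
        return int(self.insertions_per_family)


@dataclass
class SimulationTruth:
    """Machine-readable record of every planted effect."""

    seed: int
    upregulated_families: List[str]
    insertions: List[dict]          # family, chrom, start, end, strand, enriched
    te_lfc: Dict[str, float]
    gene_lfc: Dict[str, float]
    gene_near_te: Dict[str, bool]
    enrichment_factor: float
    depletion_factor: float
    domain_width: int
    het_region: str
    consensus_lengths: Dict[str, int]
    library_factors: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1 or self.depletion_factor < 1:
            raise ValueError("enrichment and depletion factors must be >= 1")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with one of the 3 others."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        codes = np.searchsorted(BASES, arr[hit])
        shifted = (codes + rng.integers(1, 4, size=hit.sum())) % 4
        arr[hit] = BASES[shifted]
    return arr.tobytes().decode()


def simulate_genome(config: SimConfig) -> Tuple[Genome, InsertionSet, pd.DataFrame,
                                                Dict[str, str], SimulationTruth,
                                                PipelineConfig]:
    """Build the synthetic reference with planted TE copies and genes.

    Returns (genome, insertions, gene table, consensus sequences, truth,
    pipeline config carrying the het_region). The heterochromatic control
    region sits in the middle of the last autosome; insertions avoid it by
    a margin wide enough to leave control bins untouched.
    """
    root = np.random.SeedSequence(config.seed)
    rng_bg, rng_te, rng_pos, rng_gene = [
        np.random.default_rng(s) for s in root.spawn(4)]

    autosomes = [f"chr{i + 1}" for i in range(config.n_chrom)]
    sequences = {c: _random_seq(rng_bg, config.chrom_length) for c in autosomes}
    sequences[config.mito_name] = _random_seq(rng_bg, config.mito_length)

    consensus = {
        fam: _random_seq(rng_te, int(rng_te.integers(*config.te_length_range)))
        for fam in config.families
    }

    het_chrom = autosomes[-1]
    het_length = min(config.het_region_length, config.chrom_length // 3)
    het_start = (config.chrom_length - het_length) // 2
    het_region = GenomicInterval(het_chrom, het_start, het_start + het_length)
    margin = 15_000  # keeps control bins > control_min_distance from insertions

    # non-overlapping, well-separated insertion placement; margins shrink on
    # small demo genomes so placement stays feasible
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in autosomes}
    occupied[het_chrom].append((het_start - margin, het_region.end + margin))
    edge = min(25_000, max(1_000, config.chrom_length // 6))
    pad = min(6_000, max(500, config.chrom_length // 12))

    def place(length: int) -> Tuple[str, int]:
        for _ in range(2000):
            chrom = autosomes[int(rng_pos.integers(0, len(autosomes)))]
            hi = config.chrom_length - length - edge
            if hi <= edge:
                continue
            pos = int(rng_pos.integers(edge, hi))
            if all(pos + length + pad <= s or pos >= e + pad
                   for s, e in occupied[chrom]):
                occupied[chrom].append((pos, pos + length))
                return chrom, pos
        raise RuntimeError("insertions requested beyond available space")

    insertions: List[Tuple[str, GenomicInterval]] = []
    truth_insertions: List[dict] = []
    for fam in config.families:
        for _ in range(config.insertion_count(fam)):
            copy = _diverge(rng_te, consensus[fam], config.divergence)
            chrom, pos = place(len(copy))
            strand = "+" if rng_pos.random() < 0.5 else "-"
            seq = sequences[chrom]
            insert_seq = copy if strand == "+" else copy.translate(
                str.maketrans("ACGT", "TGCA"))[::-1]
            sequences[chrom] = seq[:pos] + insert_seq + seq[pos + len(copy):]
            iv = GenomicInterval(chrom, pos, pos + len(copy), strand)
            insertions.append((fam, iv))
            truth_insertions.append({
                "family": fam, "chrom": chrom, "start": pos,
                "end": pos + len(copy), "strand": strand, "enriched": True,
            })
    insertion_set = InsertionSet(insertions)

    upregulated = [f for f in DEFAULT_UPREGULATED_FAMILIES if f in config.families]
    up_points = [(iv.chrom, iv.center) for fam, iv in insertions if fam in upregulated]

    # genes: a configured fraction with TSS planted inside an insertion window
    gene_rows = []
    gene_near: Dict[str, bool] = {}
    planted_near: Dict[str, bool] = {}
    n_near_target = int(round(config.n_genes * config.tss_near_fraction))
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        strand = "+" if rng_gene.random() < 0.5 else "-"
        planted = g < n_near_target and bool(up_points)
        if planted:
            chrom, center = up_points[int(rng_gene.integers(0, len(up_points)))]
            tss = int(center + rng_gene.integers(-9_000, 14_000))
            tss = int(np.clip(tss, 0, config.chrom_length - 1))
        else:
            chrom = autosomes[int(rng_gene.integers(0, len(autosomes)))]
            tss = int(rng_gene.integers(0, config.chrom_length))
        planted_near[gene_id] = planted
        gene_rows.append((gene_id, chrom, tss, strand))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])

    # truth proximity by the same rule the pipeline applies (reference
    # orientation, defaults 10 kb up / 15 kb down)
    for row in genes.itertuples():
        near = any(chrom == row.chrom and center - 10_000 <= row.tss < center + 15_000
                   for chrom, center in up_points)
        gene_near[row.gene_id] = bool(near)

    # secondary upregulation is planted on the deliberately-near subset only:
    # genes that merely land near an insertion by chance stay null, keeping
    # gene-based size factors honest at small genome scales
    te_lfc = {fam: (config.te_lfc if fam in upregulated else 0.0)
              for fam in config.families}
    gene_lfc = {gid: (config.gene_secondary_lfc if planted_near[gid] else 0.0)
                for gid in genes["gene_id"]}

    genome = Genome(sequences, mito_name=config.mito_name)
    truth = SimulationTruth(
        seed=config.seed,
        upregulated_families=upregulated,
        insertions=truth_insertions,
        te_lfc=te_lfc,
        gene_lfc=gene_lfc,
        gene_near_te=gene_near,
        enrichment_factor=config.enrichment_factor,
        depletion_factor=config.depletion_factor,
        domain_width=config.domain_width,
        het_region=f"{het_region.chrom}:{het_region.start}-{het_region.end}",
        consensus_lengths={f: len(s) for f, s in consensus.items()},
    )
    pipeline_config = PipelineConfig(het_region=het_region, seed=config.seed)
    return genome, insertion_set, genes, consensus, truth, pipeline_config


# --------------------------------------------------------------------------
# ChIP fragment simulation

def _domain_rate(mark: str, condition: str, family: str, truth: SimulationTruth,
                 config: SimConfig) -> float:
    """Fragment-density multiplier inside an insertion domain."""
    e, d = truth.enrichment_factor, truth.depletion_factor
    upregulated = family in truth.upregulated_families
    if mark == "H3K9me3":
        if condition == "knockdown" and upregulated:
            return e / d
        return e
    # active mark: baseline in control, gained on de-repressed insertions in KD
    base = config.active_mark_baseline
    if condition == "knockdown" and upregulated:
        return base * d
    return base


def simulate_chip(
    genome: Genome,
    insertions: InsertionSet,
    truth: SimulationTruth,
    condition: str,
    mark: str = "H3K9me3",
    replicates: int = 2,
    depth: int = 100_000,
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
) -> List[AlignmentRecord]:
    """Draw single-end reads whose fragment midpoints follow the planted model.

    The midpoint density is a piecewise-constant mixture: uniform background
    over every contig (including the mito contig) plus flat-top enrichment
    domains centered on insertion midpoints. Reads carry mapq 255 except a
    planted multimapper fraction at mapq 0; a duplicate fraction is injected
    by replaying already-drawn reads.
    """
    if condition not in ("control", "knockdown"):
        raise ValueError("condition must be 'control' or 'knockdown'")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    cfg = config or SimConfig()
    seed = cfg.seed if seed is None else seed
    stream = zlib.crc32(f"{condition}/{mark}".encode())  # stable across runs
    root = np.random.SeedSequence((seed, stream))
    up_width = cfg.upregulated_domain_width or cfg.domain_width
    half_frag = cfg.fragment_length // 2
    read_len = cfg.read_length

    # piecewise segments: (chrom, start, end, rate)
    segments: List[Tuple[str, int, int, float]] = [
        (chrom, 0, length, 1.0) for chrom, length in genome.lengths.items()]
    for fam, iv in insertions:
        rate = _domain_rate(mark, condition, fam, truth, cfg)
        width = up_width if fam in truth.upregulated_families else cfg.domain_width
        if rate != 1.0:
            lo = max(0, iv.center - width // 2)
            hi = min(genome.length(iv.chrom), iv.center + width // 2)
            segments.append((iv.chrom, lo, hi, rate - 1.0))  # additive on background

    weights = np.array([(end - start) * rate for _, start, end, rate in segments])
    prob = weights / weights.sum()

    chrom_names = list(genome.sequences)
    chrom_code = {name: i for i, name in enumerate(chrom_names)}
    chrom_len = np.array([genome.length(c) for c in chrom_names])
    seg_code = np.array([chrom_code[c] for c, _, _, _ in segments])
    seg_start = np.array([s for _, s, _, _ in segments])
    seg_end = np.array([e for _, _, e, _ in segments])

    records: List[AlignmentRecord] = []
    for rep, child in enumerate(root.spawn(replicates), start=1):
        rng = np.random.default_rng(child)
        sample = f"{mark}_{condition}_rep{rep}"
        seg_draws = rng.multinomial(depth, prob)
        # vectorized midpoint draw: uniform within each selected segment
        chosen = np.repeat(np.arange(len(segments)), seg_draws)
        u = rng.random(depth)
        mids = (seg_start[chosen]
                + (u * (seg_end[chosen] - seg_start[chosen])).astype(np.int64))
        chroms = seg_code[chosen]
        order = rng.permutation(depth)
        mids, chroms = mids[order], chroms[order]
        plus = rng.random(depth) < 0.5
        multi = rng.random(depth) < cfg.multimapper_fraction
        starts = np.where(plus, mids - half_frag, mids + half_frag - read_len)
        ends = starts + read_len
        valid = (starts >= 0) & (ends <= chrom_len[chroms])
        rep_records = [
            AlignmentRecord(
                GenomicInterval(chrom_names[c], int(s), int(e),
                                "+" if p else "-"),
                mapq=0 if m else 255, sample=sample)
            for c, s, e, p, m in zip(chroms[valid], starts[valid], ends[valid],
                                     plus[valid], multi[valid])]
        n_dup = int(round(len(rep_records) * cfg.duplicate_fraction))
        if n_dup:
            originals = rng.integers(0, len(rep_records), size=n_dup)
            rep_records.extend(
                dataclasses.replace(rep_records[int(j)], is_duplicate=True)
                for j in originals)
        records.extend(rep_records)
    return records


# --------------------------------------------------------------------------
# RNA-seq count simulation

def simulate_rnaseq(
    truth: SimulationTruth,
    replicates: int = 4,
    depth: int = 1_000_000,
    dispersion: float = 0.05,
    config: Optional[SimConfig] = None,
    seed: Optional[int] = None,
    library_factors: Optional[Dict[str, float]] = None,
):
    """Negative-binomial counts for genes and TE families with planted lfc.

    mean = depth * baseline_fraction * library_factor * 2**(lfc * [KD]);
    var = mean + dispersion * mean**2. Baseline abundances are log-normal.
    Returns a :class:`te_insite.expression.CountMatrix`.
    """
    from .expression import CountMatrix

    if replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    cfg = config or SimConfig()
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence((seed, 2_718_281))
    rng_base, rng_counts = [np.random.default_rng(s) for s in root.spawn(2)]

    gene_ids = sorted(truth.gene_lfc)
    te_ids = sorted(truth.te_lfc)
    feature_ids = gene_ids + te_ids
    classes = ["gene"] * len(gene_ids) + ["te_family"] * len(te_ids)
    lengths = np.array(
        [cfg.gene_length] * len(gene_ids)
        + [truth.consensus_lengths.get(t, cfg.gene_length) for t in te_ids],
        dtype=float)
    lfc = np.array([truth.gene_lfc[g] for g in gene_ids]
                   + [truth.te_lfc[t] for t in te_ids])

    baseline = rng_base.lognormal(mean=0.0, sigma=1.0, size=len(feature_ids))
    baseline /= baseline.sum()

    samples, conditions, columns = [], {}, []
    for condition in ("control", "knockdown"):
        for rep in range(1, replicates + 1):
            name = f"rna_{condition}_rep{rep}"
            samples.append(name)
            conditions[name] = condition
            lib = (library_factors or {}).get(name, 1.0)
            mean = depth * baseline * lib
            if condition == "knockdown":
                mean = mean * np.power(2.0, lfc)
            # NB with var = m + a m^2  ->  n = 1/a, p = n / (n + m)
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mean)
            columns.append(rng_counts.negative_binomial(n_param, p_param))
    counts = np.column_stack(columns)
    return CountMatrix(
        feature_ids=feature_ids, classes=classes, lengths=lengths,
        samples=samples, conditions=conditions, counts=counts)


# --------------------------------------------------------------------------
# Bundle writer

def write_simulation(
    out_dir: str,
    sim_config: SimConfig,
    chip_depth: int = 50_000,
    chip_replicates: int = 2,
    rna_replicates: int = 4,
    rna_depth: int = 500_000,
    marks: Sequence[str] = ("H3K9me3",),
) -> Dict[str, object]:
    """Simulate a full dataset and write every artifact as plain text."""
    from .genomic_core.config import parse_region

    os.makedirs(out_dir, exist_ok=True)
    genome, insertions, genes, consensus, truth, pconf = simulate_genome(sim_config)

    gio.write_fasta(os.path.join(out_dir, "genome.fa"), genome.sequences)
    gio.write_fasta(os.path.join(out_dir, "consensus.fa"), consensus)
    gio.write_insertions(os.path.join(out_dir, "insertions.bed"), insertions)
    gio.write_bed(os.path.join(out_dir, "het_region.bed"),
                  [("het", parse_region(truth.het_region))])
    gio.write_gene_table(os.path.join(out_dir, "genes.tsv"), genes)

    alignment_paths = {}
    for mark in marks:
        for condition in ("control", "knockdown"):
            records = simulate_chip(
                genome, insertions, truth, condition, mark=mark,
                replicates=chip_replicates, depth=chip_depth, config=sim_config)
            path = os.path.join(out_dir, f"chip_{mark}_{condition}.tsv")
            gio.write_alignments(path, records)
            alignment_paths[(mark, condition)] = path

    counts = simulate_rnaseq(truth, replicates=rna_replicates, depth=rna_depth,
                             config=sim_config)
    counts.to_frame().to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return {
        "genome": genome, "insertions": insertions, "genes": genes,
        "consensus": consensus, "truth": truth, "pipeline_config": pconf,
        "counts": counts, "alignment_paths": alignment_paths,
    }
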