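"""Mappability-filtered 1-kb bin analysis and CPM coverage tracks.

The genome is tiled in fixed-width non-overlapping bins, bins with low
mean mappability are dropped, survivors are categorized by proximity to TE
insertions (upregulated families, other families, or a distal
heterochromatic control region), per-sample fragment counts are normalized
for mappability and library size, replicates are averaged per condition,
and each category is compared between conditions with a rank-sum test.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core.config import PipelineConfig
from .genomic_core.genome import AlignmentRecord, Genome, InsertionSet, fragment_transform
from .genomic_core.intervals import GenomicInterval
from .mappability import MappabilityTrack, region_mean_mappability

CATEGORIES = ("near_upregulated_te", "near_other_te", "control_het", "unassigned")


def make_filtered_bins(genome: Genome, track: MappabilityTrack,
                       config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Tile chromosomes into bins and keep those with mappability above the floor.

    Bins start at 0 in steps of ``bin_width``; a trailing partial bin is
    dropped. Bins with mean mappability <= ``mappability_min_frac`` are
    removed.
    """
    cfg = config or PipelineConfig()
    width = cfg.bin_width
    rows = []
    for chrom, length in genome.lengths.items():
        vec = track.values[chrom]
        for start in range(0, length - width + 1, width):
            mean_map = float(vec[start:start + width].mean())
            if mean_map > cfg.mappability_min_frac:
                rows.append((chrom, start, start + width, mean_map))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_mappability"])
    bins.index.name = "bin"
    return bins


def _gap_to_bin(start: int, end: int, point: int) -> int:
    """0 if the point lies inside the bin, else distance to the nearest edge."""
    return max(0, start - point, point - end)


def assign_categories(bins: pd.DataFrame, insertions: InsertionSet,
                      config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Mutually exclusive bin categories with fixed precedence.

    near_upregulated_te beats near_other_te beats control_het; a control
    bin must lie inside the configured heterochromatin region and farther
    than ``control_min_distance`` from every insertion of any family.
    """
    cfg = config or PipelineConfig()
    up = set(cfg.upregulated_families)
    other = set(cfg.other_families)
    het = cfg.require_het_region()
    points = insertions.reference_points()

    categories: List[str] = []
    for row in bins.itertuples():
        gaps_up, gaps_other, gaps_all = [], [], []
        for family, chrom, center, _ in points:
            if chrom != row.chrom:
                continue
            gap = _gap_to_bin(row.start, row.end, center)
            gaps_all.append(gap)
            if family in up:
                gaps_up.append(gap)
            elif family in other:
                gaps_other.append(gap)
        if gaps_up and min(gaps_up) <= cfg.proximity_radius:
            categories.append("near_upregulated_te")
        elif gaps_other and min(gaps_other) <= cfg.proximity_radius:
            categories.append("near_other_te")
        elif (row.chrom == het.chrom and row.start >= het.start and row.end <= het.end
              and (not gaps_all or min(gaps_all) > cfg.control_min_distance)):
            categories.append("control_het")
        else:
            categories.append("unassigned")
    out = bins.copy()
    out["category"] = categories
    return out


def library_sizes(records: Sequence[AlignmentRecord], genome: Genome,
                  min_mapq: int = 0) -> Dict[str, int]:
    """Retained fragments per sample, excluding the mitochondrial contig."""
    sizes: Dict[str, int] = {}
    for rec in records:
        if rec.mapq < min_mapq:
            continue
        if genome.mito_name is not None and rec.interval.chrom == genome.mito_name:
            continue
        sizes[rec.sample] = sizes.get(rec.sample, 0) + 1
    return sizes


def bin_signal(
    records: Sequence[AlignmentRecord],
    bins: pd.DataFrame,
    genome: Genome,
    config: Optional[PipelineConfig] = None,
    conditions: Optional[Dict[str, str]] = None,
    assign: str = "midpoint",
    extend_center: bool = True,
) -> pd.DataFrame:
    """Per-sample raw counts and normalized signal per bin.

    Records must already be deduplicated and mapq-filtered. Each fragment
    (extended and re-centered when ``extend_center``) is assigned to the
    single bin containing its midpoint (``assign="midpoint"``, conserving
    totals) or to every overlapping bin (``assign="overlap"``).
    norm_signal = (count / mean_mappability) * 1e6 / library size, with the
    library size excluding the mito contig. When ``conditions`` maps sample
    -> condition, per-condition replicate means are appended.
    """
    cfg = config or PipelineConfig()
    if assign not in ("midpoint", "overlap"):
        raise ValueError("assign must be 'midpoint' or 'overlap'")
    samples = sorted({rec.sample for rec in records})
    lib = library_sizes(records, genome)
    for smp in samples:
        if lib.get(smp, 0) == 0:
            raise ValueError(f"sample {smp!r} has zero retained fragments "
                             "outside the mito contig")

    width = cfg.bin_width
    counts = np.zeros((len(bins), len(samples)), dtype=np.int64)
    sample_col = {s: j for j, s in enumerate(samples)}
    if assign == "midpoint":
        counts += _midpoint_counts(records, bins, genome, cfg, sample_col,
                                   extend_center)
    else:
        index_of: Dict[tuple, int] = {
            (row.chrom, row.start): i
            for i, row in enumerate(bins.itertuples(index=False))}
        for rec in records:
            frag = (fragment_transform(rec, cfg.fragment_length, True, genome)
                    if extend_center else rec.interval)
            j = sample_col[rec.sample]
            first = (frag.start // width) * width
            for bin_start in range(first, frag.end, width):
                i = index_of.get((frag.chrom, bin_start))
                if i is not None:
                    counts[i, j] += 1

    out = bins.copy()
    mappability = out["mean_mappability"].to_numpy()
    for smp in samples:
        j = sample_col[smp]
        out[f"count_{smp}"] = counts[:, j]
        out[f"norm_{smp}"] = counts[:, j] / mappability * 1e6 / lib[smp]
    if conditions:
        by_cond: Dict[str, List[str]] = {}
        for smp in samples:
            cond = conditions.get(smp)
            if cond is not None:
                by_cond.setdefault(cond, []).append(smp)
        for cond, members in sorted(by_cond.items()):
            out[f"mean_{cond}"] = np.mean(
                [out[f"norm_{m}"].to_numpy() for m in members], axis=0)
    return out


def _midpoint_counts(records, bins, genome, cfg, sample_col, extend_center):
    """Vectorized fragment-midpoint bin counting.

    Replicates :func:`fragment_transform` integer arithmetic (extension,
    re-centering, boundary clipping) on flat arrays; bins tile from 0 at a
    fixed width, so a midpoint's candidate bin is midpoint // width and
    filtered-out bins are looked up as absent.
    """
    width = cfg.bin_width
    chrom_names = list(genome.sequences)
    chrom_code = {name: i for i, name in enumerate(chrom_names)}
    chrom_len = np.array([genome.length(c) for c in chrom_names])

    n = len(records)
    chroms = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    minus = np.empty(n, dtype=bool)
    samples = np.empty(n, dtype=np.int64)
    for i, rec in enumerate(records):
        iv = rec.interval
        chroms[i] = chrom_code[iv.chrom]
        starts[i], ends[i] = iv.start, iv.end
        minus[i] = iv.strand == "-"
        samples[i] = sample_col[rec.sample]

    if extend_center:
        frag = cfg.fragment_length
        lengths = chrom_len[chroms]
        fs = np.where(minus, np.maximum(0, ends - frag), starts)
        fe = np.where(minus, ends, np.minimum(lengths, starts + frag))
        mid_frag = (fs + fe) // 2
        read_len = ends - starts
        cs = np.maximum(0, mid_frag - read_len // 2)
        ce = np.minimum(lengths, cs + read_len)
        cs = np.maximum(0, np.minimum(cs, ce - 1))
        mids = (cs + ce) // 2
    else:
        mids = (starts + ends) // 2

    # global bin-number lookup across chromosomes
    offsets = np.concatenate([[0], np.cumsum(chrom_len // width + 1)])
    lookup = np.full(offsets[-1], -1, dtype=np.int64)
    for i, row in enumerate(bins.itertuples(index=False)):
        lookup[offsets[chrom_code[row.chrom]] + row.start // width] = i
    rows = lookup[offsets[chroms] + mids // width]
    ok = rows >= 0
    counts = np.zeros((len(bins), len(sample_col)), dtype=np.int64)
    np.add.at(counts, (rows[ok], samples[ok]), 1)
    return counts


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # rank-sum degenerates when every value ties
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_categories(
    table: pd.DataFrame,
    kd_column: str,
    ctrl_column: str,
    fc_significance: float = 2.0,
    p_significance: float = 1e-3,
    pseudocount: Optional[float] = None,
) -> pd.DataFrame:
    """Category-wise knockdown vs control comparison.

    fold_change = (median kd + c) / (median ctrl + c); the pseudocount c
    (default: half the smallest nonzero signal) only engages when one of
    the medians is zero, so fully-scaled comparisons stay exact. p comes
    from a two-sided Wilcoxon rank-sum test of the per-bin values. The
    significance flag
    requires a >2-fold difference in median (either direction) and
    p below the cutoff. Categories with < 2 bins report NA statistics.
    """
    if pseudocount is None:
        pooled = np.concatenate([table[kd_column].to_numpy(),
                                 table[ctrl_column].to_numpy()])
        nonzero = pooled[pooled > 0]
        pseudocount = float(nonzero.min()) / 2.0 if len(nonzero) else 0.5
    rows = []
    for category in CATEGORIES:
        sub = table[table["category"] == category]
        if category == "unassigned":
            continue
        kd = sub[kd_column].to_numpy(dtype=float)
        ctrl = sub[ctrl_column].to_numpy(dtype=float)
        if len(sub) < 2:
            rows.append({"category": category, "n_bins": len(sub),
                         "median_fold_change": np.nan, "p": np.nan,
                         "significant": False})
            continue
        med_kd, med_ctrl = np.median(kd), np.median(ctrl)
        c = 0.0 if (med_kd > 0 and med_ctrl > 0) else pseudocount
        fc = (med_kd + c) / (med_ctrl + c)
        p = _ranksum_p(kd, ctrl)
        rows.append({
            "category": category,
            "n_bins": len(sub),
            "median_fold_change": float(fc),
            "p": p,
            "significant": bool((fc > fc_significance or fc < 1.0 / fc_significance)
                                and p < p_significance),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Per-base CPM coverage

def coverage_track(
    records: Sequence[AlignmentRecord],
    genome: Genome,
    config: Optional[PipelineConfig] = None,
    mode: str = "chip",
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-sample per-base CPM coverage tracks.

    ``chip`` mode extends reads to the expected fragment length and centers
    them before accumulating coverage; ``rna`` mode uses raw read spans.
    Values are scaled by 1e6 / (retained reads excluding the mito contig),
    so a library of a single read carries exactly 1e6 on its covered bases.
    """
    cfg = config or PipelineConfig()
    if mode not in ("chip", "rna"):
        raise ValueError("mode must be 'chip' or 'rna'")
    lib = library_sizes(records, genome)
    tracks: Dict[str, Dict[str, np.ndarray]] = {}
    for rec in records:
        iv = (fragment_transform(rec, cfg.fragment_length, True, genome)
              if mode == "chip" else rec.interval)
        per_chrom = tracks.setdefault(rec.sample, {})
        vec = per_chrom.get(iv.chrom)
        if vec is None:
            vec = per_chrom.setdefault(iv.chrom, np.zeros(genome.length(iv.chrom)))
        vec[iv.start:iv.end] += 1.0
    for sample, per_chrom in tracks.items():
        scale = 1e6 / lib[sample] if lib.get(sample) else 0.0
        for chrom in per_chrom:
            per_chrom[chrom] *= scale
    return tracks


def consensus_coverage(
    records: Sequence[AlignmentRecord],
    consensus_lengths: Dict[str, int],
    config: Optional[PipelineConfig] = None,
    sense_only: bool = False,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-consensus per-base CPM coverage of consensus-space alignments.

    With ``sense_only`` only plus-strand (sense) reads contribute. Scaling
    is per million total retained reads of the sample (sense and antisense).
    """
    for rec in records:
        if rec.interval.chrom not in consensus_lengths:
            raise ValueError(
                f"alignment targets unknown consensus {rec.interval.chrom!r}")
    totals: Dict[str, int] = {}
    for rec in records:
        totals[rec.sample] = totals.get(rec.sample, 0) + 1
    tracks: Dict[str, Dict[str, np.ndarray]] = {}
    for rec in records:
        if sense_only and rec.interval.strand != "+":
            continue
        per_cons = tracks.setdefault(rec.sample, {})
        vec = per_cons.get(rec.interval.chrom)
        if vec is None:
            vec = per_cons.setdefault(
                rec.interval.chrom, np.zeros(consensus_lengths[rec.interval.chrom]))
        vec[rec.interval.start:rec.interval.end] += 1.0
    for sample, per_cons in tracks.items():
        for name in per_cons:
            per_cons[name] *= 1e6 / totals[sample]
    return tracks
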