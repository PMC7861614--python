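"""Expression quantification and de-repression calling.

Strand-aware unique-read counting over genes and TE consensus sequences,
median-of-ratios size factors, RPKM/CPM on the robust library size, fold
changes with a pluggable significance test, threshold-based de-repression
classification, and the delta-delta-CT fold change for qPCR.

The negative-binomial GLM / shrinkage machinery of full DE engines is
deliberately out of scope; the built-in test is a two-sample t-test on
log2 normalized counts and any callable with the same signature can be
plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_core.config import PipelineConfig
from .genomic_core.genome import AlignmentRecord
from .genomic_core.intervals import GenomicInterval, overlap_bp

FEATURE_CLASSES = ("gene", "te_family")
STRANDEDNESS_MODES = ("forward", "reverse", "unstranded")
LABELS = ("upregulated", "downregulated", "not_significant", "low_expression")


@dataclass(frozen=True)
class Feature:
    """A countable annotation unit: a gene interval or a TE consensus."""

    feature_id: str
    cls: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"feature class must be one of {FEATURE_CLASSES}")

    @property
    def length(self) -> int:
        return self.interval.width


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with feature lengths and classes."""

    feature_ids: List[str]
    classes: List[str]
    lengths: np.ndarray
    samples: List[str]
    conditions: Dict[str, str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError("counts shape does not match features x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be > 0")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.feature_ids, columns=self.samples)
        frame.insert(0, "class", self.classes)
        frame.insert(1, "length", self.lengths.astype(int))
        frame.index.name = "feature_id"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   conditions: Optional[Dict[str, str]] = None) -> "CountMatrix":
        samples = [c for c in frame.columns if c not in ("class", "length")]
        return cls(
            feature_ids=list(frame.index.astype(str)),
            classes=list(frame["class"]),
            lengths=frame["length"].to_numpy(dtype=float),
            samples=samples,
            conditions=conditions or {},
            counts=frame[samples].to_numpy(),
        )


def count_features(
    records: Sequence[AlignmentRecord],
    features: Sequence[Feature],
    strandedness: str,
    min_mapq: int,
    samples: Optional[Sequence[str]] = None,
    conditions: Optional[Dict[str, str]] = None,
) -> CountMatrix:
    """Unique-read counting with largest-overlap assignment.

    A record is counted iff its mapq passes, its orientation matches the
    feature under the requested strandedness, and it overlaps at least one
    feature; a record overlapping several features goes to the single
    feature with the largest overlap (ties broken by annotation order), so
    each record contributes at most one count.
    """
    if strandedness not in STRANDEDNESS_MODES:
        raise ValueError(f"strandedness must be one of {STRANDEDNESS_MODES}")
    if not features:
        raise ValueError("features must be non-empty")
    if samples is None:
        seen = dict.fromkeys(rec.sample for rec in records)
        samples = list(seen)
    sample_index = {s: j for j, s in enumerate(samples)}

    by_chrom: Dict[str, List[Tuple[int, Feature]]] = {}
    for idx, feat in enumerate(features):
        by_chrom.setdefault(feat.interval.chrom, []).append((idx, feat))

    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    for rec in records:
        if rec.mapq < min_mapq or rec.sample not in sample_index:
            continue
        best_idx, best_ov = -1, 0
        for idx, feat in by_chrom.get(rec.interval.chrom, ()):
            if strandedness == "forward" and rec.interval.strand != feat.interval.strand:
                continue
            if strandedness == "reverse":
                pair = {rec.interval.strand, feat.interval.strand}
                if pair != {"+", "-"}:
                    continue
            ov = overlap_bp(rec.interval, feat.interval)
            if ov > best_ov:
                best_idx, best_ov = idx, ov
        if best_idx >= 0:
            counts[best_idx, sample_index[rec.sample]] += 1

    return CountMatrix(
        feature_ids=[f.feature_id for f in features],
        classes=[f.cls for f in features],
        lengths=np.array([f.length for f in features], dtype=float),
        samples=list(samples),
        conditions=conditions or {},
        counts=counts,
    )


# --------------------------------------------------------------------------
# Normalization

def size_factors(counts: CountMatrix,
                 reference_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Robust median-of-ratios size factors.

    s_j = median over features f of counts[f, j] / geomean_k counts[f, k],
    taken over features with no zero count in any sample. ``reference_mask``
    restricts the reference feature set (e.g. genes only, with the factors
    then reused for the combined gene + TE matrix).
    """
    mat = counts.counts.astype(float)
    if reference_mask is not None:
        mat = mat[np.asarray(reference_mask, dtype=bool)]
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "size-factor normalization failed: no feature has nonzero "
            "counts in every sample")
    ref = mat[usable]
    log_geomean = np.log(ref).mean(axis=1)
    # median taken in linear ratio space (log-space medians differ when the
    # median interpolates between two features)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    if not (factors > 0).all():
        raise ValueError("size factors must be positive")
    return factors


def rpkm_cpm(counts: CountMatrix, s: np.ndarray) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """CPM and RPKM on size-factor-normalized counts.

    Normalized counts n = counts / s; robust library size L_j = sum_f n_fj;
    CPM = n * 1e6 / L_j; RPKM = CPM * 1e3 / feature length.
    """
    s = np.asarray(s, dtype=float)
    norm = counts.counts / s[None, :]
    lib = norm.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size after normalization")
    cpm = norm * 1e6 / lib[None, :]
    rpkm = cpm * 1e3 / counts.lengths[:, None]
    cpm_df = pd.DataFrame(cpm, index=counts.feature_ids, columns=counts.samples)
    rpkm_df = pd.DataFrame(rpkm, index=counts.feature_ids, columns=counts.samples)
    return cpm_df, rpkm_df


# --------------------------------------------------------------------------
# Differential expression

TestFunc = Callable[[np.ndarray, np.ndarray], np.ndarray]


def log_t_test(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Built-in pluggable test: two-sample t-test per feature on log2 values.

    Inputs are log2(normalized count + pseudocount) matrices with samples in
    columns. Features with zero variance in both groups get p = 1 when the
    means are equal, else p = 0 (the t statistic degenerates).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(group_a, group_b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(group_a.mean(axis=1), group_b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    return multipletests(p, method="fdr_bh")[1]


def fold_change_and_test(
    counts: CountMatrix,
    s: np.ndarray,
    groups: Dict[str, str],
    treatment: str,
    control: str,
    test: TestFunc = log_t_test,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature log2 fold change, p and BH-adjusted p.

    lfc = log2((mean normalized treatment + c) / (mean normalized control + c)).
    """
    treat_cols = [j for j, smp in enumerate(counts.samples) if groups.get(smp) == treatment]
    ctrl_cols = [j for j, smp in enumerate(counts.samples) if groups.get(smp) == control]
    if len(treat_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each condition needs >= 2 samples")
    labelled = {groups[smp] for smp in counts.samples if smp in groups}
    if labelled - {treatment, control}:
        raise ValueError(f"unexpected condition labels: {sorted(labelled - {treatment, control})}")

    norm = counts.counts / np.asarray(s, dtype=float)[None, :]
    treat, ctrl = norm[:, treat_cols], norm[:, ctrl_cols]
    lfc = np.log2(treat.mean(axis=1) + pseudocount) - np.log2(ctrl.mean(axis=1) + pseudocount)
    p = np.clip(test(np.log2(treat + pseudocount), np.log2(ctrl + pseudocount)), 0.0, 1.0)
    padj = bh_adjust(p)

    _, rpkm = rpkm_cpm(counts, s)
    return pd.DataFrame({
        "feature_id": counts.feature_ids,
        "class": counts.classes,
        "lfc": lfc,
        "p": p,
        "padj": padj,
        "rpkm_mean": rpkm.mean(axis=1).to_numpy(),
    }).set_index("feature_id")


def classify_de(de: pd.DataFrame, config: Optional[PipelineConfig] = None) -> pd.Series:
    """Label features by the de-repression thresholds.

    upregulated: lfc > threshold, padj < threshold, mean RPKM > threshold;
    downregulated symmetric; low_expression whenever mean RPKM fails the
    floor regardless of the statistics.
    """
    cfg = config or PipelineConfig()
    labels = np.full(len(de), "not_significant", dtype=object)
    lfc = de["lfc"].to_numpy()
    padj = de["padj"].to_numpy()
    rpkm = de["rpkm_mean"].to_numpy()
    significant = padj < cfg.padj_threshold
    labels[significant & (lfc > cfg.lfc_threshold)] = "upregulated"
    labels[significant & (lfc < -cfg.lfc_threshold)] = "downregulated"
    labels[rpkm <= cfg.rpkm_threshold] = "low_expression"
    return pd.Series(labels, index=de.index, name="label")


def run_de(counts: CountMatrix, groups: Dict[str, str], treatment: str,
           control: str, config: Optional[PipelineConfig] = None,
           test: TestFunc = log_t_test,
           size_factor_reference: str = "gene") -> pd.DataFrame:
    """Full DE pass: size factors (gene reference when present) -> table.

    Mirrors the study design where gene-derived size factors are reused for
    the combined gene + transposon matrix.
    """
    cfg = config or PipelineConfig()
    classes = np.asarray(counts.classes)
    mask = classes == size_factor_reference
    s = size_factors(counts, reference_mask=mask if mask.any() else None)
    de = fold_change_and_test(counts, s, groups, treatment, control,
                              test=test, pseudocount=cfg.pseudocount)
    de["label"] = classify_de(de, cfg)
    return de


# --------------------------------------------------------------------------
# qPCR

def ddct_fold_change(ct_target: float, ct_ref: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Delta-delta-CT relative fold change: 2**-((Tt - Tr) - (Ct - Cr))."""
    ddct = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
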