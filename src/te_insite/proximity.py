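"""Promoter-to-insertion proximity annotation and fold-change stratification.

A gene is "near" a TE insertion when its TSS falls within a fixed window
upstream/downstream of the insertion reference point (the interval
midpoint). Clustered insertions (reference points closer than a minimum
gap) are excluded before annotation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_core.config import PipelineConfig
from .genomic_core.genome import InsertionSet


def filter_clustered(insertions: InsertionSet, min_gap: int) -> InsertionSet:
    """Drop every insertion with another reference point < min_gap away.

    The rule is symmetric: both members of a close pair are removed, so
    survivors are pairwise >= min_gap apart. Idempotent.
    """
    points = insertions.reference_points()
    keep = []
    for i, (_, chrom_i, center_i, _) in enumerate(points):
        clustered = any(
            j != i and chrom_j == chrom_i and abs(center_j - center_i) < min_gap
            for j, (_, chrom_j, center_j, _) in enumerate(points)
        )
        keep.append(not clustered)
    return InsertionSet([ins for ins, ok in zip(insertions.insertions, keep) if ok])


def _window(center: int, strand: str, up: int, down: int,
            orientation: str) -> Tuple[int, int]:
    """Half-open TSS acceptance window around an insertion reference point."""
    if orientation == "insertion" and strand == "-":
        return center - down, center + up
    return center - up, center + down


def annotate_tss_proximity(
    genes: pd.DataFrame,
    insertions: InsertionSet,
    config: Optional[PipelineConfig] = None,
    families: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Flag genes whose TSS lies near an insertion of the given families.

    ``families`` defaults to the configured upregulated family list. The
    window is oriented by the insertion's strand when
    ``config.window_orientation == "insertion"`` (reference orientation for
    strandless insertions), else always in reference orientation. Returns
    the gene table extended with near_te, nearest_family and the signed
    reference-orientation distance from reference point to TSS.
    """
    cfg = config or PipelineConfig()
    wanted = set(families if families is not None else cfg.upregulated_families)
    points = [p for p in insertions.reference_points() if p[0] in wanted]

    near_te: List[bool] = []
    nearest_family: List[Optional[str]] = []
    distance: List[float] = []
    for row in genes.itertuples():
        tss = int(row.tss)
        best: Optional[Tuple[int, str]] = None
        for family, chrom, center, strand in points:
            if chrom != row.chrom:
                continue
            lo, hi = _window(center, strand, cfg.tss_window_up,
                             cfg.tss_window_down, cfg.window_orientation)
            if lo <= tss < hi:
                d = tss - center
                if best is None or abs(d) < abs(best[0]):
                    best = (d, family)
        near_te.append(best is not None)
        nearest_family.append(best[1] if best else None)
        distance.append(float(best[0]) if best else np.nan)

    out = genes.copy()
    out["near_te"] = near_te
    out["nearest_family"] = nearest_family
    out["distance"] = distance
    return out


def stratified_fraction(
    de: pd.DataFrame,
    prox: pd.DataFrame,
    strata: Sequence[float],
    rpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Fraction of TE-proximal genes per fold-change stratum.

    Genes are restricted to mean RPKM > ``rpkm_min``, then partitioned by
    lfc into the half-open bins defined by the edge sequence ``strata``
    (with open outer bins). Empty strata report NaN, not 0.
    """
    edges = list(strata)
    if sorted(edges) != edges:
        raise ValueError("strata edges must be sorted")
    merged = prox.set_index("gene_id").join(
        de[de["class"] == "gene"][["lfc", "rpkm_mean"]], how="inner")
    merged = merged[merged["rpkm_mean"] > rpkm_min]

    full_edges = [-np.inf] + edges + [np.inf]
    rows = []
    for lo, hi in zip(full_edges[:-1], full_edges[1:]):
        mask = (merged["lfc"] >= lo) & (merged["lfc"] < hi)
        n_genes = int(mask.sum())
        n_near = int(merged.loc[mask, "near_te"].sum())
        rows.append({
            "stratum": f"[{lo:g}, {hi:g})",
            "lfc_low": lo,
            "lfc_high": hi,
            "n_genes": n_genes,
            "n_near": n_near,
            "fraction": (n_near / n_genes) if n_genes else np.nan,
        })
    return pd.DataFrame(rows)
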