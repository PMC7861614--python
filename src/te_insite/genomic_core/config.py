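"""Pipeline configuration: every numeric constant in one validated place."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import List, Optional

from .intervals import GenomicInterval

DEFAULT_UPREGULATED_FAMILIES = ("gypsy", "mdg1", "blood", "297", "412")
DEFAULT_OTHER_FAMILIES = ("Juan", "Bari1", "1360", "pogo", "Burdock", "diver")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open) into an interval."""
    try:
        chrom, span = text.rsplit(":", 1)
        start_s, end_s = span.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"cannot parse region {text!r} (expected chrom:start-end)") from exc


def format_region(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class PipelineConfig:
    # mappability
    kmer_length: int = 50
    pair_gap_shift: int = 146
    mappability_min_frac: float = 0.5
    # ChIP fragments / bins
    fragment_length: int = 260
    bin_width: int = 1000
    proximity_radius: int = 1000
    control_min_distance: int = 10000
    # TSS proximity
    tss_window_up: int = 10000
    tss_window_down: int = 15000
    cluster_min_gap: int = 5000
    window_orientation: str = "insertion"  # or "reference"
    # differential expression
    lfc_threshold: float = 2.0
    padj_threshold: float = 0.05
    rpkm_threshold: float = 1.0
    pseudocount: float = 0.5
    # meta-profile matrices
    matrix_before: int = 10000
    matrix_after: int = 15000
    profile_bin: int = 5
    heatmap_bin: int = 50
    n_bootstrap: int = 200
    ci_level: float = 0.95
    heatmap_cap_percentile: float = 99.0
    # mapping-quality thresholds operationalising read uniqueness
    mapq_rna: int = 50
    mapq_chip: int = 255
    # TE family groups
    upregulated_families: List[str] = field(
        default_factory=lambda: list(DEFAULT_UPREGULATED_FAMILIES))
    other_families: List[str] = field(
        default_factory=lambda: list(DEFAULT_OTHER_FAMILIES))
    # study-specific control region (no universal default; set per dataset)
    het_region: Optional[GenomicInterval] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kmer_length", "fragment_length", "bin_width",
                     "proximity_radius", "control_min_distance",
                     "tss_window_up", "tss_window_down", "cluster_min_gap",
                     "matrix_before", "matrix_after", "profile_bin",
                     "heatmap_bin", "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pair_gap_shift < 0:
            raise ValueError("pair_gap_shift must be >= 0")
        if not 0 < self.mappability_min_frac <= 1:
            raise ValueError("mappability_min_frac must be in (0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        for name in ("lfc_threshold", "padj_threshold", "rpkm_threshold",
                     "pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.heatmap_cap_percentile <= 100:
            raise ValueError("heatmap_cap_percentile must be in (0, 100]")
        if self.window_orientation not in ("insertion", "reference"):
            raise ValueError("window_orientation must be 'insertion' or 'reference'")
        overlap = set(self.upregulated_families) & set(self.other_families)
        if overlap:
            raise ValueError(
                f"upregulated and other family lists overlap: {sorted(overlap)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(data)
        if isinstance(payload.get("het_region"), str):
            payload["het_region"] = parse_region(payload["het_region"])
        elif isinstance(payload.get("het_region"), dict):
            payload["het_region"] = GenomicInterval(**payload["het_region"])
        return cls(**payload)

    def to_dict(self) -> dict:
        data = asdict(self)
        if self.het_region is not None:
            data["het_region"] = format_region(self.het_region)
        return data

    def require_het_region(self) -> GenomicInterval:
        if self.het_region is None:
            raise ValueError(
                "config key 'het_region' is required for the control bin "
                "category but is not set")
        return self.het_region
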