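"""Insertion-anchored signal matrices, bootstrap profiles and heatmap prep."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genomic_core.genome import InsertionSet


@dataclass
class MetaMatrix:
    """Insertions x positional-bins signal matrix around reference points.

    Columns span ``[-before, +after)`` relative to each insertion center in
    steps of ``bin_size``; positions beyond chromosome bounds contribute 0.
    """

    values: np.ndarray
    row_ids: List[str]
    before: int
    after: int
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.before + self.after) // self.bin_size
        if self.values.shape != (len(self.row_ids), expected):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {expected} columns")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Left edge of each positional bin relative to the reference point."""
        return np.arange(-self.before, self.after, self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.row_ids,
                             columns=[str(p) for p in self.positions])
        frame.index.name = "row_id"
        return frame


def reference_point_matrix(
    track: Dict[str, np.ndarray],
    points: InsertionSet,
    before: int,
    after: int,
    bin_size: int,
) -> MetaMatrix:
    """Mean per-base signal in positional bins around each insertion center.

    Out-of-chromosome positions count as zero signal (but still divide the
    bin mean), matching missing-data-as-zero semantics.
    """
    if (before + after) % bin_size != 0:
        raise ValueError("bin_size must divide before + after")
    n_cols = (before + after) // bin_size
    rows, row_ids = [], []
    for idx, (family, iv) in enumerate(points):
        if iv.chrom not in track:
            raise ValueError(f"no track for chromosome {iv.chrom!r}")
        vec = track[iv.chrom]
        ref = iv.center
        window = np.zeros(before + after)
        lo, hi = ref - before, ref + after
        src_lo, src_hi = max(0, lo), min(len(vec), hi)
        if src_hi > src_lo:
            window[src_lo - lo:src_hi - lo] = vec[src_lo:src_hi]
        rows.append(window.reshape(n_cols, bin_size).mean(axis=1))
        row_ids.append(f"{family}:{iv.chrom}:{ref}|{idx}")
    values = np.array(rows) if rows else np.empty((0, n_cols))
    return MetaMatrix(values, row_ids, before, after, bin_size)


def profile_bootstrap(
    matrix: MetaMatrix,
    n_boot: int = 200,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Column means with percentile-bootstrap confidence intervals.

    Rows (insertions) are resampled with replacement; the reported mean is
    the plain column mean (the bootstrap affects only the interval), and the
    CI is clipped to contain it. Deterministic under a fixed seed. With
    fewer than 2 rows the CI degenerates to the mean.
    """
    mean = matrix.values.mean(axis=0) if matrix.n_rows else np.zeros(matrix.values.shape[1])
    if matrix.n_rows < 2:
        ci_low = ci_high = mean.copy()
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, matrix.n_rows, size=(n_boot, matrix.n_rows))
        boot_means = matrix.values[idx].mean(axis=1)  # (n_boot, n_cols)
        alpha = (1.0 - ci_level) / 2.0
        ci_low = np.percentile(boot_means, 100 * alpha, axis=0)
        ci_high = np.percentile(boot_means, 100 * (1 - alpha), axis=0)
        ci_low = np.minimum(ci_low, mean)
        ci_high = np.maximum(ci_high, mean)
    return pd.DataFrame({
        "position": matrix.positions,
        "mean": mean,
        "ci_low": ci_low,
        "ci_high": ci_high,
    })


def heatmap_prepare(
    matrix: MetaMatrix,
    cap_percentile: float = 99.0,
    sort_reference: Optional[MetaMatrix] = None,
) -> MetaMatrix:
    """Cap extreme values and order rows for heatmap display.

    The cap is the given percentile over *all* matrix values; rows are
    sorted by decreasing row mean of ``sort_reference`` (default: the
    matrix itself), preserving row identity. Idempotent.
    """
    ref = sort_reference if sort_reference is not None else matrix
    if ref.row_ids != matrix.row_ids:
        raise ValueError("sort reference rows do not match matrix rows")
    capped = matrix.values.copy()
    if capped.size:
        # order-statistic quantile: re-capping an already-capped matrix is a
        # no-op (interpolated percentiles drift downward on reapplication)
        cap = np.quantile(capped, cap_percentile / 100.0, method="lower")
        capped = np.minimum(capped, cap)
    order = np.argsort(-ref.values.mean(axis=1), kind="stable")
    return MetaMatrix(
        capped[order],
        [matrix.row_ids[i] for i in order],
        matrix.before, matrix.after, matrix.bin_size,
    )
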