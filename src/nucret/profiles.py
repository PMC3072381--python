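"""Anchor-centered average profiles and per-gene heatmap matrices.

Profiles cover ~+/-2 kb around each anchor in window-width bins.  The
span is widened to an odd number of bins so the anchor sits in the
central bin (27 bins x 150 bp = 4,050 bp for the 4-kb default).
Minus-strand anchors are orientation-flipped so that "downstream" always
means the direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from nucret.seqcomp import ParameterError, WindowGrid


def _n_bins(span: int, bin_bp: int) -> int:
    n = -(-span // bin_bp)  # ceil
    return n if n % 2 == 1 else n + 1


@dataclass
class MetaProfile:
    """Mean track value per relative bin, with contributing-anchor counts."""

    offsets: np.ndarray  # bp offset of each bin start from the anchor bin
    mean: np.ndarray     # NaN where no anchor contributed
    count: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.count}
        )


def _anchor_rows(
    values: np.ndarray,
    grid: WindowGrid,
    anchors: list[tuple[str, int, str]],
    span: int,
    bin_bp: int,
) -> np.ndarray:
    """Matrix of track values around each anchor (NaN where unavailable)."""
    nb = _n_bins(span, bin_bp)
    half = nb // 2
    rel = np.arange(-half, half + 1)
    rows = np.full((len(anchors), nb), np.nan)
    for r, (chrom, pos, strand) in enumerate(anchors):
        try:
            ci = grid.chrom_index(chrom)
        except KeyError:
            continue
        center = pos // grid.width
        if not 0 <= center < int(grid.counts[ci]):
            continue
        offs = rel if strand == "+" else -rel
        idx = center + offs
        ok = (idx >= 0) & (idx < int(grid.counts[ci]))
        flat = int(grid.offsets[ci]) + idx[ok]
        rows[r, ok] = values[flat]
    return rows


def meta_profile(
    values,
    grid: WindowGrid,
    anchors: list[tuple[str, int, str]],
    span: int = 4000,
    bin_bp: int | None = None,
) -> MetaProfile:
    """Average a per-window track around a list of oriented anchors.

    ``values`` may contain NaN for excluded windows; those windows (and
    out-of-range bins) do not contribute to the mean or the count.
    """
    if not anchors:
        raise ParameterError("empty anchor list")
    values = np.asarray(values, dtype=float)
    bin_bp = bin_bp or grid.width
    if bin_bp != grid.width:
        raise ParameterError("profile bin width must equal the grid width")
    rows = _anchor_rows(values, grid, anchors, span, bin_bp)
    count = np.sum(~np.isnan(rows), axis=0)
    total = np.nansum(rows, axis=0)
    mean = np.divide(total, count, out=np.full(count.shape, np.nan),
                     where=count > 0)
    half = rows.shape[1] // 2
    offsets = np.arange(-half, half + 1) * bin_bp
    return MetaProfile(offsets, mean, count)


@dataclass
class GeneProfileMatrix:
    """Per-gene profile rows in a fixed (possibly clustered) order."""

    gene_ids: list[str]
    offsets: np.ndarray
    values: np.ndarray  # shape (genes, bins)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.offsets,
        )


def _cluster_order(matrix: np.ndarray) -> np.ndarray:
    """Deterministic leaf order from average-linkage Euclidean clustering."""
    if matrix.shape[0] < 3:
        return np.arange(matrix.shape[0])
    filled = matrix.copy()
    col_mean = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_rows, nan_cols = np.where(np.isnan(filled))
    filled[nan_rows, nan_cols] = col_mean[nan_cols]
    link = hierarchy.linkage(pdist(filled, metric="euclidean"), method="average")
    return np.asarray(hierarchy.leaves_list(link))


def gene_profile_matrix(
    values,
    grid: WindowGrid,
    genes,
    span: int = 4000,
    bin_bp: int | None = None,
    order_by: GeneProfileMatrix | None = None,
) -> GeneProfileMatrix:
    """Per-gene rows of a track around each gene's canonical TSS.

    When ``order_by`` is given (a companion matrix, e.g. GC content over
    the same genes), rows are reordered by hierarchical clustering of
    the companion so paired heatmaps share one gene ordering; otherwise
    input order is kept.
    """
    anchors = [(g.chrom, g.tss, g.strand) for g in genes]
    if not anchors:
        raise ParameterError("empty gene list")
    values = np.asarray(values, dtype=float)
    bin_bp = bin_bp or grid.width
    rows = _anchor_rows(values, grid, anchors, span, bin_bp)
    half = rows.shape[1] // 2
    offsets = np.arange(-half, half + 1) * bin_bp
    ids = [g.gene_id for g in genes]
    if order_by is not None:
        if order_by.gene_ids != ids:
            raise ValueError("order_by matrix must cover the same genes in order")
        order = _cluster_order(order_by.values)
        rows = rows[order]
        ids = [ids[k] for k in order]
    return GeneProfileMatrix(ids, offsets, rows)
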