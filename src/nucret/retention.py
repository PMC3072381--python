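"""Fragment-center counting, retention scores, and enrichment-region calling.

Reads are 5'-end records (chrom, position, strand).  Each read is shifted
by half the fragment length (default 75 bp) in the direction of
sequencing to estimate the fragment center, and centers are counted in
the fixed window grid.  The per-window normalized retention score
compares the nucleosome library to a depth-matched genomic input:
``S = (n - i) / sqrt(n + i)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from nucret.seqcomp import Genome, ParameterError, WindowGrid

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "five_prime", "strand"]


class ReadRecord(NamedTuple):
    """A sequenced read reduced to its 5' end and strand."""

    chrom: str
    five_prime: int
    strand: str


@dataclass
class RetentionParams:
    """Constants of the retention workflow (defaults as published)."""

    shift_bp: int = 75
    window_bp: int = 150
    min_total_reads: int = 5
    caller_window_bp: int = 300
    caller_step_bp: int = 150
    caller_alpha: float = 0.05
    caller_correction: str = "bh"  # "bh" or "none"
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shift_bp", "window_bp", "min_total_reads",
                     "caller_window_bp", "caller_step_bp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.caller_alpha < 1:
            raise ParameterError("caller_alpha must be in (0, 1)")


def reads_from_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table missing columns {missing}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("read strand must be '+' or '-'")
    return df[READ_COLUMNS].reset_index(drop=True)


def read_reads_tsv(path) -> pd.DataFrame:
    """Read a 3-column (chrom, five_prime, strand) TSV, with or without header."""
    first = pd.read_csv(str(path), sep="\t", nrows=1, header=None)
    header = 0 if str(first.iloc[0, 0]) == "chrom" else None
    df = pd.read_csv(str(path), sep="\t", header=header)
    df.columns = READ_COLUMNS[: df.shape[1]]
    return reads_from_dataframe(df)


def reads_from_bed6(path) -> pd.DataFrame:
    """Convert BED6 alignments to 5'-end records.

    For minus-strand intervals the 5' end is ``end - 1`` (the last base
    of the half-open interval).
    """
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BED6 requires 6 columns (strand in column 6)")
    chrom, start, end, strand = df[0], df[1], df[2], df[5]
    five = np.where(strand == "+", start, end - 1)
    return pd.DataFrame(
        {"chrom": chrom, "five_prime": five.astype(np.int64), "strand": strand}
    )


def shift_read_to_center(read: ReadRecord, shift_bp: int = 75) -> int:
    """Fragment-center position of a 5'-end record.

    Plus-strand reads shift downstream (+shift), minus-strand upstream
    (-shift).  May fall outside the chromosome; callers drop those.
    """
    if read.strand == "+":
        return read.five_prime + shift_bp
    if read.strand == "-":
        return read.five_prime - shift_bp
    raise ValueError(f"invalid strand {read.strand!r}")


def shift_reads(reads: pd.DataFrame, shift_bp: int = 75) -> np.ndarray:
    """Vectorized fragment-center positions for a read table."""
    sign = np.where(reads["strand"].to_numpy() == "+", 1, -1)
    return reads["five_prime"].to_numpy(dtype=np.int64) + sign * shift_bp


def dedup_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (chrom, five_prime, strand) records to one."""
    return reads.drop_duplicates(subset=READ_COLUMNS).reset_index(drop=True)


def count_centers_in_windows(
    reads: pd.DataFrame,
    grid: WindowGrid,
    shift_bp: int = 75,
    dedup: bool = False,
) -> np.ndarray:
    """Per-window counts of shifted fragment centers.

    Centers outside the tiled span and reads on chromosomes absent from
    the grid are dropped (the latter with a logged warning).
    """
    if dedup:
        reads = dedup_reads(reads)
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    known = set(grid.chrom_names)
    unknown = set(reads["chrom"].unique()) - known
    if unknown:
        logger.warning("skipping reads on unknown chromosomes: %s", sorted(unknown))
    centers = shift_reads(reads, shift_bp)
    chroms = reads["chrom"].to_numpy()
    for chrom in grid.chrom_names:
        sel = chroms == chrom
        if not sel.any():
            continue
        idx = grid.locate(chrom, centers[sel])
        idx = idx[idx >= 0]
        np.add.at(counts, idx, 1)
    return counts


def subsample_reads(
    reads: pd.DataFrame, target_total: int, seed: int
) -> pd.DataFrame:
    """Uniform sample of exactly ``target_total`` reads, without replacement."""
    n = len(reads)
    if target_total > n:
        raise ParameterError(f"target_total {target_total} exceeds read count {n}")
    if target_total == n:
        return reads.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=target_total, replace=False)
    keep.sort()
    return reads.iloc[keep].reset_index(drop=True)


def normalized_retention_score(nuc_count, input_count):
    """``(n - i) / sqrt(n + i)``; undefined (error) when n + i == 0."""
    n = np.asarray(nuc_count, dtype=float)
    i = np.asarray(input_count, dtype=float)
    tot = n + i
    if np.any(tot <= 0):
        raise ParameterError("retention score undefined for n + i == 0")
    out = (n - i) / np.sqrt(tot)
    return float(out) if out.ndim == 0 else out


def low_coverage_filter(
    nuc_counts: np.ndarray, input_counts: np.ndarray, min_total: int = 5
) -> np.ndarray:
    """Keep-mask: True where nuc + input >= ``min_total``."""
    return (np.asarray(nuc_counts) + np.asarray(input_counts)) >= min_total


@dataclass
class RetentionScoreTrack:
    """Per-window normalized retention scores with exclusion flags."""

    grid: WindowGrid
    nuc_count: np.ndarray
    input_count: np.ndarray
    score: np.ndarray          # NaN where nuc + input == 0
    low_coverage: np.ndarray   # True where nuc + input < min_total
    excluded: np.ndarray       # True where repetitive or N-containing

    def analysis_mask(self) -> np.ndarray:
        return ~self.low_coverage & ~self.excluded

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.window_bounds()
        df["nuc"] = self.nuc_count
        df["input"] = self.input_count
        df["score"] = self.score
        df["low_coverage"] = self.low_coverage
        df["excluded"] = self.excluded
        return df


def retention_score_track(
    nuc_counts: np.ndarray,
    input_counts: np.ndarray,
    grid: WindowGrid,
    min_total: int = 5,
    excluded: np.ndarray | None = None,
) -> RetentionScoreTrack:
    """Assemble the per-window score track with coverage/exclusion flags."""
    nuc = np.asarray(nuc_counts, dtype=np.int64)
    inp = np.asarray(input_counts, dtype=np.int64)
    tot = nuc + inp
    score = np.full(grid.n_windows, np.nan)
    nz = tot > 0
    score[nz] = (nuc[nz] - inp[nz]) / np.sqrt(tot[nz])
    if excluded is None:
        excluded = np.zeros(grid.n_windows, dtype=bool)
    return RetentionScoreTrack(
        grid, nuc, inp, score, ~low_coverage_filter(nuc, inp, min_total),
        np.asarray(excluded, dtype=bool),
    )


def binomial_enrichment_score(
    signal_count: int, input_count: int, depth_ratio: float
) -> float:
    """Binomial enrichment of a signal library over its input control.

    Returns ``-log10 P(X >= signal | n = signal + input, p = depth_ratio)``
    where ``depth_ratio`` is the signal library's share of the combined
    sequencing depth.  The exact tail form is a declared choice: the
    source analysis names the distribution but not the formula.
    """
    if not 0 < depth_ratio < 1:
        raise ParameterError("depth_ratio must be in (0, 1)")
    if signal_count < 0 or input_count < 0:
        raise ParameterError("counts must be non-negative")
    total = signal_count + input_count
    if total == 0 or signal_count == 0:
        return 0.0
    tail = stats.binom.sf(signal_count - 1, total, depth_ratio)
    tail = max(float(tail), np.finfo(float).tiny)
    return max(0.0, -np.log10(tail))


def call_enriched_regions(
    nuc_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    genome: Genome,
    params: RetentionParams | None = None,
) -> pd.DataFrame:
    """Call regions where nucleosome reads significantly exceed input.

    A one-sided binomial test is applied to fragment-center counts in
    sliding windows (width ``caller_window_bp``, step ``caller_step_bp``):
    under the null, each of the n + i reads in a window is a nucleosome
    read with probability equal to the nucleosome library's share of
    total depth.  Windows passing the (Benjamini-Hochberg by default)
    threshold are merged when overlapping; each region's score is the
    max -log10(adjusted p) of its windows.

    Returns a frame with columns chrom, start, end, enrichment_score.
    """
    params = params or RetentionParams()
    if len(nuc_reads) == 0 or len(input_reads) == 0:
        raise ParameterError("both read sets must be non-empty")
    depth_ratio = len(nuc_reads) / (len(nuc_reads) + len(input_reads))

    win, step = params.caller_window_bp, params.caller_step_bp
    nuc_centers = shift_reads(nuc_reads, params.shift_bp)
    inp_centers = shift_reads(input_reads, params.shift_bp)
    nchrom = nuc_reads["chrom"].to_numpy()
    ichrom = input_reads["chrom"].to_numpy()
    all_starts, all_chrom, all_n, all_i = [], [], [], []
    for chrom, seq in genome.chroms.items():
        length = len(seq)
        if length < win:
            continue
        starts = np.arange(0, length - win + 1, step, dtype=np.int64)
        nc = np.sort(nuc_centers[(nchrom == chrom)])
        ic = np.sort(inp_centers[(ichrom == chrom)])
        nc = nc[(nc >= 0) & (nc < length)]
        ic = ic[(ic >= 0) & (ic < length)]
        ncnt = np.searchsorted(nc, starts + win) - np.searchsorted(nc, starts)
        icnt = np.searchsorted(ic, starts + win) - np.searchsorted(ic, starts)
        all_starts.append(starts)
        all_chrom.append(np.repeat(chrom, starts.size))
        all_n.append(ncnt)
        all_i.append(icnt)
    starts = np.concatenate(all_starts)
    chroms = np.concatenate(all_chrom)
    n = np.concatenate(all_n)
    i = np.concatenate(all_i)
    tot = n + i

    pvals = np.ones(starts.size)
    nz = tot > 0
    pvals[nz] = stats.binom.sf(n[nz] - 1, tot[nz], depth_ratio)

    if params.caller_correction == "bh":
        adj = stats.false_discovery_control(pvals, method="bh")
    elif params.caller_correction == "none":
        adj = pvals
    else:
        raise ParameterError(
            f"unknown caller_correction {params.caller_correction!r}"
        )
    hit = adj <= params.caller_alpha
    if not hit.any():
        return pd.DataFrame(columns=["chrom", "start", "end", "enrichment_score"])

    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(adj, np.finfo(float).tiny))
    regions = []
    for chrom in genome.names:
        sel = hit & (chroms == chrom)
        if not sel.any():
            continue
        s = starts[sel]
        sc = score[sel]
        order = np.argsort(s)
        s, sc = s[order], sc[order]
        cur_start, cur_end, cur_score = int(s[0]), int(s[0]) + win, float(sc[0])
        for j in range(1, s.size):
            if s[j] < cur_end:  # overlapping window: extend
                cur_end = int(s[j]) + win
                cur_score = max(cur_score, float(sc[j]))
            else:
                regions.append((chrom, cur_start, cur_end, cur_score))
                cur_start, cur_end, cur_score = int(s[j]), int(s[j]) + win, float(sc[j])
        regions.append((chrom, cur_start, cur_end, cur_score))
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "enrichment_score"]
    )
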