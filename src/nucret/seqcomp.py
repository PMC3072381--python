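"""Windowed base-composition tracks, k-mer uniqueness masks, and CpG islands.

The genome is tiled into fixed-width non-overlapping windows (default
150 bp) anchored at position 0 of each chromosome; a trailing partial
window is dropped.  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")

# base -> 2-bit code; N -> -1 (invalid inside k-mers)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class ParameterError(ValueError):
    """Raised when an operation receives an out-of-contract parameter."""


@dataclass
class Genome:
    """A set of named chromosome sequences over the {A,C,G,T,N} alphabet.

    Input is normalized to upper case; any other letter is rejected.
    """

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for name, seq in self.chroms.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} is empty")
            if not set(seq) <= _ALPHABET:
                bad = sorted(set(seq) - _ALPHABET)
                raise ValueError(f"chromosome {name!r} has invalid letters {bad}")
            norm[name] = seq
        self.chroms = norm

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path, line_width: int = 70) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chroms.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(recs)

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping fixed-width windows tiling each chromosome from 0.

    Windows are indexed by a single flat integer running over chromosomes
    in insertion order; ``offsets[c]`` is the flat index of the first
    window of chromosome ``c``.
    """

    width: int
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    counts: np.ndarray = field(repr=False)   # windows per chromosome
    offsets: np.ndarray = field(repr=False)  # flat index of first window

    @classmethod
    def from_genome(cls, genome: Genome, width: int = 150) -> "WindowGrid":
        if width <= 0:
            raise ParameterError(f"window width must be >= 1, got {width}")
        names = tuple(genome.names)
        lengths = tuple(genome.length(c) for c in names)
        counts = np.array([ln // width for ln in lengths], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
        return cls(width, names, lengths, counts, offsets)

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.n_windows

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not on grid") from None

    def locate(self, chrom: str, pos) -> np.ndarray:
        """Flat window index for genomic position(s); -1 if untiled.

        Positions past the last full window (the dropped partial tail)
        map to -1, as do negative positions.
        """
        ci = self.chrom_index(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        idx = pos // self.width
        flat = self.offsets[ci] + idx
        ok = (pos >= 0) & (idx < self.counts[ci])
        return np.where(ok, flat, -1)

    def window_bounds(self) -> pd.DataFrame:
        """Per-window (chrom, start, end) table in flat-index order."""
        chroms = np.repeat(np.array(self.chrom_names, dtype=object), self.counts)
        starts = np.concatenate(
            [np.arange(n, dtype=np.int64) * self.width for n in self.counts]
        ) if self.n_windows else np.empty(0, dtype=np.int64)
        return pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + self.width}
        )

    def iter_chrom_slices(self) -> Iterator[tuple[str, int, slice]]:
        """Yield (chrom, chrom_index, flat-index slice) per chromosome."""
        for ci, name in enumerate(self.chrom_names):
            lo = int(self.offsets[ci])
            yield name, ci, slice(lo, lo + int(self.counts[ci]))


def make_windows(genome: Genome, width: int = 150) -> WindowGrid:
    """Tile every chromosome into non-overlapping ``width``-bp windows."""
    return WindowGrid.from_genome(genome, width)


@dataclass
class CompositionTrack:
    """Per-window base composition: G+C count, CpG count, N count, uniqueness."""

    grid: WindowGrid
    gc_count: np.ndarray
    cpg_count: np.ndarray
    n_count: np.ndarray
    unique: np.ndarray | None = None  # True where no repeated k-mer

    @property
    def gc_fraction(self) -> np.ndarray:
        return self.gc_count / self.grid.width

    @property
    def has_n(self) -> np.ndarray:
        return self.n_count > 0

    def analysis_mask(self) -> np.ndarray:
        """Windows usable for correlation/ROC: no N, no repeated k-mer."""
        mask = ~self.has_n
        if self.unique is not None:
            mask &= self.unique
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        df = self.grid.window_bounds()
        df["gc"] = self.gc_count
        df["cpg"] = self.cpg_count
        df["n"] = self.n_count
        df["unique"] = self.unique if self.unique is not None else True
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_base_counts(genome: Genome, grid: WindowGrid) -> CompositionTrack:
    """Count G+C, within-window CpG dinucleotides, and N per window.

    CpGs are counted on the forward strand only ("CG" is its own reverse
    complement) and never across a window boundary.
    """
    w = grid.width
    gc = np.empty(grid.n_windows, dtype=np.int64)
    cpg = np.empty(grid.n_windows, dtype=np.int64)
    nn = np.empty(grid.n_windows, dtype=np.int64)
    for chrom, ci, sl in grid.iter_chrom_slices():
        nwin = int(grid.counts[ci])
        if nwin == 0:
            continue
        codes = _encode(genome[chrom])[: nwin * w]
        tiles = codes.reshape(nwin, w)
        gc[sl] = ((tiles == 1) | (tiles == 2)).sum(axis=1)
        nn[sl] = (tiles == -1).sum(axis=1)
        # CG dinucleotide fully inside the window: pairs (j, j+1), j < w-1
        cpg[sl] = ((tiles[:, :-1] == 1) & (tiles[:, 1:] == 2)).sum(axis=1)
    return CompositionTrack(grid, gc, cpg, nn)


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code of every k-mer plus a validity mask (no N inside)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        vals = (vals << 2) | (c & 3)
        valid &= c >= 0
    return vals, valid


def kmer_uniqueness_mask(
    genome: Genome, grid: WindowGrid, k: int = 20
) -> np.ndarray:
    """Flag windows whose every k-mer occurs exactly once genome-wide.

    A k-mer's multiplicity is the number of occurrences of the k-mer
    plus those of its reverse complement anywhere in the genome
    (mappability of unstranded short reads).  k-mers containing N are
    unmappable and count as non-unique.
    """
    if k <= 0 or k > grid.width:
        raise ParameterError(f"k must be in 1..{grid.width}, got {k}")
    fwd_codes: list[np.ndarray] = []
    rc_codes: list[np.ndarray] = []
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in grid.chrom_names:
        codes = _encode(genome[chrom])
        f, fv = _kmer_codes(codes, k)
        # reverse complement: complement (3 - code, N stays invalid), reversed
        comp = np.where(codes >= 0, 3 - codes, -1)[::-1]
        r, rv = _kmer_codes(comp, k)
        per_chrom[chrom] = (f, fv)
        fwd_codes.append(f[fv])
        rc_codes.append(r[rv])
    pool = np.concatenate(fwd_codes + rc_codes) if fwd_codes else np.empty(0, np.int64)
    uniq, counts = np.unique(pool, return_counts=True)

    out = np.ones(grid.n_windows, dtype=bool)
    w = grid.width
    for chrom, ci, sl in grid.iter_chrom_slices():
        nwin = int(grid.counts[ci])
        if nwin == 0:
            continue
        f, fv = per_chrom[chrom]
        mult = np.zeros(f.size, dtype=np.int64)
        if f.size:
            pos = np.searchsorted(uniq, f)
            pos = np.clip(pos, 0, max(uniq.size - 1, 0))
            hit = uniq.size > 0
            if hit:
                found = uniq[pos] == f
                mult[found] = counts[pos[found]]
        bad = (mult != 1) | ~fv  # repeated or N-containing k-mer start
        # window unique iff no bad k-mer start in [start, start + w - k]
        cs = np.concatenate([[0], np.cumsum(bad)])
        starts = np.arange(nwin, dtype=np.int64) * w
        lo = starts
        hi = np.minimum(starts + w - k + 1, bad.size)
        out[sl] = (cs[hi] - cs[lo]) == 0
    return out


@dataclass(frozen=True)
class CpGIsland:
    """A GC-rich, CpG-dense interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _interval_stats(codes: np.ndarray, start: int, end: int) -> tuple[float, float]:
    seg = codes[start:end]
    c = int((seg == 1).sum())
    g = int((seg == 2).sum())
    cpg = int(((seg[:-1] == 1) & (seg[1:] == 2)).sum())
    length = end - start
    gc_frac = (c + g) / length
    oe = (cpg * length) / (c * g) if c * g > 0 else 0.0
    return gc_frac, oe


def detect_cpg_islands(
    genome: Genome,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Call maximal CpG islands with the classical threshold definition.

    Every ``min_len``-bp seed window with GC fraction >= ``min_gc`` and
    observed/expected CpG = (#CpG * L)/(#C * #G) >= ``min_oe`` is found;
    overlapping seeds are merged greedily and the merged interval is
    trimmed from the ends until it satisfies all thresholds itself.
    Output intervals are sorted and non-overlapping.
    """
    if min_len <= 0 or min_gc <= 0 or min_oe <= 0:
        raise ParameterError("island thresholds must be positive")
    islands: list[CpGIsland] = []
    for chrom, seq in genome.chroms.items():
        codes = _encode(seq)
        L = codes.size
        if L < min_len:
            continue
        is_c = (codes == 1).astype(np.int64)
        is_g = (codes == 2).astype(np.int64)
        is_cpg = np.zeros(L, dtype=np.int64)
        is_cpg[:-1] = (codes[:-1] == 1) & (codes[1:] == 2)
        cs_c = np.concatenate([[0], np.cumsum(is_c)])
        cs_g = np.concatenate([[0], np.cumsum(is_g)])
        cs_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

        n_seed = L - min_len + 1
        s = np.arange(n_seed)
        c = cs_c[s + min_len] - cs_c[s]
        g = cs_g[s + min_len] - cs_g[s]
        # CpG fully inside the seed: pair starts in [s, s+min_len-1)
        cpg = cs_cpg[s + min_len - 1] - cs_cpg[s]
        gc_ok = (c + g) / min_len >= min_gc
        prod = c * g
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(prod > 0, cpg * min_len / np.maximum(prod, 1), 0.0)
        qual = gc_ok & (oe >= min_oe)
        qpos = s[qual]
        if qpos.size == 0:
            continue
        # group seeds whose intervals [q, q+min_len) overlap
        breaks = np.flatnonzero(np.diff(qpos) >= min_len) + 1
        for group in np.split(qpos, breaks):
            start = int(group[0])
            end = int(group[-1]) + min_len
            gc_frac, oe_val = _interval_stats(codes, start, end)
            while (end - start > min_len) and (gc_frac < min_gc or oe_val < min_oe):
                left_at = codes[start] in (0, 3)
                right_at = codes[end - 1] in (0, 3)
                if left_at or not right_at:
                    start += 1
                else:
                    end -= 1
                gc_frac, oe_val = _interval_stats(codes, start, end)
            if gc_frac >= min_gc and oe_val >= min_oe and end - start >= min_len:
                islands.append(CpGIsland(chrom, start, end, gc_frac, oe_val))
    return islands


def islands_to_dataframe(islands: list[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": [i.start for i in islands],
            "end": [i.end for i in islands],
            "gc_fraction": [i.gc_fraction for i in islands],
            "obs_exp_cpg": [i.obs_exp_cpg for i in islands],
        }
    )


def write_bed(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    """Write intervals as BED3 (plus optional name/score columns)."""
    cols = [df["chrom"], df["start"], df["end"]]
    if score_col is not None:
        cols += [pd.Series(["."] * len(df)), df[score_col]]
    out = pd.concat(cols, axis=1)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a (chrom, start, end[, name, score, strand]) frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df
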