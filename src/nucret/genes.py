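"""Gene models, expression-based gene classes, and interval annotation.

Gene classes:

* ``housekeeping`` — from an externally supplied list when available,
  otherwise the fallback rule "expressed (RPKM >= threshold) in every
  surveyed tissue" (breadth == number of tissues).
* ``tissue_specific`` — expressed above threshold in exactly one tissue.
* ``developmental_TF`` — annotated with GO:0006355 (DNA-dependent
  regulation of transcription) and any GO term name containing
  "development".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucret.seqcomp import ParameterError

logger = logging.getLogger(__name__)

DEV_TF_GO_ID = "GO:0006355"
RPKM_THRESHOLD = 0.5
PRESENCE_MIN_DONORS = 7
PRESENCE_N_DONORS = 13


@dataclass
class GeneModel:
    """A TSS-anchored gene record.

    ``tss``/``tes`` are the canonical (5'-most) start and the end of the
    gene; ``transcript_tss`` lists the start sites of all transcripts.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    transcript_tss: list[int] = field(default_factory=list)
    go_terms: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if not self.transcript_tss:
            self.transcript_tss = [self.tss]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint min(tss, tes)..max(tss, tes), half-open."""
        lo, hi = sorted((self.tss, self.tes))
        return lo, hi + 1


def genes_from_tsv(path) -> list[GeneModel]:
    """Load gene models from a 6+-column TSV.

    Columns: gene_id, chrom, strand, tss, tes[, transcript_tss
    (comma-separated), go_terms (semicolon-separated ``id|name`` pairs)].
    """
    df = pd.read_csv(str(path), sep="\t")
    out = []
    for row in df.itertuples(index=False):
        tx = (
            [int(x) for x in str(row.transcript_tss).split(",")]
            if getattr(row, "transcript_tss", "") not in ("", None) and
            not pd.isna(getattr(row, "transcript_tss", np.nan))
            else []
        )
        go: set[tuple[str, str]] = set()
        raw_go = getattr(row, "go_terms", "")
        if isinstance(raw_go, str) and raw_go:
            for item in raw_go.split(";"):
                tid, _, tname = item.partition("|")
                go.add((tid, tname))
        out.append(
            GeneModel(
                str(row.gene_id), str(row.chrom), str(row.strand),
                int(row.tss), int(row.tes), tx, go,
            )
        )
    return out


def genes_to_tsv(genes: list[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "tes": g.tes,
            "transcript_tss": ",".join(str(t) for t in g.transcript_tss),
            "go_terms": ";".join(f"{tid}|{name}" for tid, name in sorted(g.go_terms)),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _nearest_gap(pos: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Distance from ``pos`` to the nearest [start, end) interval; 0 inside."""
    if starts.size == 0:
        return np.iinfo(np.int64).max
    inside = (starts <= pos) & (pos < ends)
    if inside.any():
        return 0
    left = starts - pos           # >0 when interval is to the right
    right = pos - (ends - 1)      # >0 when interval is to the left
    gaps = np.where(left > 0, left, np.where(right > 0, right, 0))
    return int(gaps.min())


def _sorted_regions_by_chrom(regions: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
        )
    return out


def tss_retained(
    gene: GeneModel, regions: pd.DataFrame, max_dist: int = 50
) -> bool:
    """True iff any transcript TSS is within ``max_dist`` bp of a region.

    Distance is the gap to the nearest region boundary, 0 inside;
    inclusive at exactly ``max_dist``.  Genes on chromosomes with no
    regions return False.
    """
    sub = regions[regions["chrom"] == gene.chrom]
    if sub.empty:
        logger.debug("gene %s: chromosome %s has no regions", gene.gene_id, gene.chrom)
        return False
    starts = sub["start"].to_numpy(np.int64)
    ends = sub["end"].to_numpy(np.int64)
    return any(
        _nearest_gap(t, starts, ends) <= max_dist for t in gene.transcript_tss
    )


def tss_retained_flags(
    genes: list[GeneModel], regions: pd.DataFrame, max_dist: int = 50
) -> np.ndarray:
    """Vector of ``tss_retained`` over a gene list."""
    by_chrom = _sorted_regions_by_chrom(regions)
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))
    out = np.zeros(len(genes), dtype=bool)
    for k, g in enumerate(genes):
        starts, ends = by_chrom.get(g.chrom, empty)
        out[k] = any(
            _nearest_gap(t, starts, ends) <= max_dist for t in g.transcript_tss
        )
    return out


def classify_region_location(
    region, genes: list[GeneModel], max_dist: int = 50
) -> str:
    """Label a region TSS / TES / other_genic / non_genic.

    Precedence is TSS > TES > other_genic; a region within ``max_dist``
    of both a start and an end site is labelled TSS.  ``region`` is any
    object with chrom/start/end attributes or a mapping with those keys.
    """
    if isinstance(region, dict):
        chrom, start, end = region["chrom"], region["start"], region["end"]
    else:
        chrom, start, end = region.chrom, region.start, region.end

    def interval_gap(lo: int, hi: int, pos: int) -> int:
        if lo <= pos < hi:
            return 0
        return lo - pos if pos < lo else pos - (hi - 1)

    near_tss = near_tes = genic = False
    for g in genes:
        if g.chrom != chrom:
            continue
        for t in g.transcript_tss:
            if interval_gap(start, end, t) <= max_dist:
                near_tss = True
        # TES: transcription end (tes for the canonical model)
        if interval_gap(start, end, g.tes) <= max_dist:
            near_tes = True
        lo, hi = g.span
        if start < hi and lo < end:
            genic = True
    if near_tss:
        return "TSS"
    if near_tes:
        return "TES"
    if genic:
        return "other_genic"
    return "non_genic"


def classify_regions(
    regions: pd.DataFrame, genes: list[GeneModel], max_dist: int = 50
) -> pd.Series:
    return pd.Series(
        [
            classify_region_location(row, genes, max_dist)
            for row in regions.itertuples(index=False)
        ],
        index=regions.index,
        name="location",
    )


def expression_breadth(
    rpkm: pd.DataFrame, threshold: float = RPKM_THRESHOLD
) -> pd.Series:
    """Number of tissues with RPKM >= threshold, per gene (rows = genes)."""
    return (rpkm >= threshold).sum(axis=1)


def is_developmental_tf(go_terms: set[tuple[str, str]]) -> bool:
    has_id = any(tid == DEV_TF_GO_ID for tid, _ in go_terms)
    has_dev = any("development" in name.lower() for _, name in go_terms)
    return has_id and has_dev


def classify_genes(
    rpkm: pd.DataFrame,
    go_terms: dict[str, set[tuple[str, str]]] | None = None,
    hk_list: set[str] | None = None,
    threshold: float = RPKM_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene class labels from expression breadth and GO annotation.

    Returns a frame indexed by gene id with columns breadth (int, -1 for
    genes without expression data never occurs here since rpkm is the
    index source), housekeeping, tissue_specific, developmental_TF
    (booleans; labels may co-occur).
    """
    go_terms = go_terms or {}
    breadth = expression_breadth(rpkm, threshold)
    n_tissues = rpkm.shape[1]
    if hk_list is not None:
        hk = breadth.index.to_series().isin(hk_list)
    else:
        hk = breadth == n_tissues
    ts = breadth == 1
    dev = pd.Series(
        [is_developmental_tf(go_terms.get(g, set())) for g in breadth.index],
        index=breadth.index,
    )
    return pd.DataFrame(
        {
            "breadth": breadth,
            "housekeeping": hk,
            "tissue_specific": ts,
            "developmental_TF": dev,
        }
    )


def sperm_mrna_present(calls) -> bool:
    """True iff mRNA is called present in >= 7 of exactly 13 donors."""
    calls = list(calls)
    if len(calls) != PRESENCE_N_DONORS:
        raise ParameterError(
            f"expected {PRESENCE_N_DONORS} donor calls, got {len(calls)}"
        )
    return sum(bool(c) for c in calls) >= PRESENCE_MIN_DONORS


def bin_genes_for_trend(
    genes: pd.DataFrame,
    sort_key: str,
    retained_col: str = "retained",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Sort genes by a key and split into contiguous equal-size bins.

    Ties are broken by stable index (gene-id) order; the remainder goes
    to the last bin.  Returns per-bin (score, total, successes, mean_key).
    """
    if len(genes) == 0:
        raise ParameterError("empty gene set")
    if n_bins > len(genes):
        raise ParameterError("more bins than genes")
    ordered = genes.sort_values(sort_key, kind="stable")
    size = len(ordered) // n_bins
    rows = []
    for b in range(n_bins):
        lo = b * size
        hi = (b + 1) * size if b < n_bins - 1 else len(ordered)
        chunk = ordered.iloc[lo:hi]
        rows.append(
            {
                "score": b,
                "total": len(chunk),
                "successes": int(chunk[retained_col].sum()),
                "mean_key": float(chunk[sort_key].mean()),
            }
        )
    return pd.DataFrame(rows)


def filter_distal_sites(
    sites: pd.DataFrame, genes: list[GeneModel], min_dist: int = 1000
) -> pd.DataFrame:
    """Retain sites at least ``min_dist`` bp from every gene span.

    A gene's span is min(tss, tes)..max(tss, tes); sites overlapping a
    gene (distance 0) are removed; the threshold is inclusive (a site
    exactly ``min_dist`` away is retained).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append(g.span)
    keep = []
    for idx, row in sites.iterrows():
        ok = True
        for lo, hi in spans.get(row["chrom"], []):
            if row["start"] < hi and lo < row["end"]:
                dist = 0
            elif row["end"] <= lo:
                dist = lo - (row["end"] - 1)
            else:
                dist = row["start"] - (hi - 1)
            if dist < min_dist:
                ok = False
                break
        keep.append(ok)
    return sites[np.array(keep, dtype=bool)].reset_index(drop=True)
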