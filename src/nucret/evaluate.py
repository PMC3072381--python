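"""ROC/AUC, contingency statistics, trend tests, and track correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nucret.seqcomp import ParameterError


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator is degenerate."""


@dataclass
class RocResult:
    """ROC points (one threshold per distinct score) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores, labels) -> RocResult:
    """ROC by sweeping distinct score thresholds in decreasing order.

    Ties are grouped at a single threshold, so the trapezoidal AUC
    equals the pairwise probability P(score+ > score-) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    npos = int(labels.sum())
    nneg = labels.size - npos
    if npos == 0 or nneg == 0:
        raise UndefinedStatisticError("AUC undefined: need both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tie-group of scores
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tp / npos, [1.0]])
    fpr = np.concatenate([[0.0], fp / nneg, [1.0]])
    thresholds = np.concatenate([[np.inf], s[cut], [-np.inf]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thresholds, auc)


def binary_predictor_point(predictor, labels) -> tuple[float, float]:
    """(sensitivity, specificity) of a boolean predictor."""
    predictor = np.asarray(predictor, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    tp = int((predictor & labels).sum())
    fn = int((~predictor & labels).sum())
    tn = int((~predictor & ~labels).sum())
    fp = int((predictor & ~labels).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedStatisticError("need both positive and negative labels")
    return tp / (tp + fn), tn / (tn + fp)


@dataclass
class Contingency2x2:
    """Label (unmethylated/methylated) x overlap (retained/not) counts."""

    unmeth_retained: int
    unmeth_not: int
    meth_retained: int
    meth_not: int

    def __post_init__(self) -> None:
        for v in (self.unmeth_retained, self.unmeth_not,
                  self.meth_retained, self.meth_not):
            if v < 0:
                raise ValueError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.unmeth_retained, self.unmeth_not],
             [self.meth_retained, self.meth_not]],
            dtype=np.int64,
        )

    @property
    def precision(self) -> float:
        """Unmethylated fraction among retained islands."""
        denom = self.unmeth_retained + self.meth_retained
        if denom == 0:
            raise UndefinedStatisticError("no retained islands: precision undefined")
        return self.unmeth_retained / denom

    @property
    def recall(self) -> float:
        """Retained fraction among unmethylated islands."""
        denom = self.unmeth_retained + self.unmeth_not
        if denom == 0:
            raise UndefinedStatisticError("no unmethylated islands: recall undefined")
        return self.unmeth_retained / denom

    @property
    def methylated_overlap_rate(self) -> float:
        """Retained fraction among methylated islands."""
        denom = self.meth_retained + self.meth_not
        if denom == 0:
            raise UndefinedStatisticError("no methylated islands")
        return self.meth_retained / denom


def _any_overlap(
    chrom: str, start: int, end: int,
    regions_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
) -> bool:
    if chrom not in regions_by_chrom:
        return False
    starts, ends = regions_by_chrom[chrom]
    k = np.searchsorted(starts, end)  # regions with start < end
    return bool((ends[:k] > start).any())


def methylation_overlap_stats(
    islands: pd.DataFrame, regions: pd.DataFrame
) -> tuple[Contingency2x2, float, float]:
    """Cross CpG-island methylation labels with retention-region overlap.

    ``islands`` needs chrom/start/end plus a boolean ``unmethylated``
    column; overlap is any >= 1 bp intersection with a region.  Returns
    (table, precision, recall).
    """
    if len(islands) == 0:
        raise ParameterError("empty island set")
    if "unmethylated" not in islands.columns:
        raise ValueError("islands need an 'unmethylated' boolean column")
    by_chrom = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for row in islands.itertuples(index=False):
        ov = _any_overlap(row.chrom, row.start, row.end, by_chrom)
        cells[(bool(row.unmethylated), ov)] += 1
    table = Contingency2x2(
        cells[(True, True)], cells[(True, False)],
        cells[(False, True)], cells[(False, False)],
    )
    return table, table.precision, table.recall


def cochran_armitage_trend(
    totals, successes, scores=None
) -> tuple[float, float]:
    """1-df chi-square test for linear trend in proportions.

    ``scores`` defaults to the bin index 0..k-1; the statistic is
    invariant under affine transformation of the scores.  Returns
    (chi2, p) with p from the upper chi-square(1) tail.
    """
    totals = np.asarray(totals, dtype=float)
    successes = np.asarray(successes, dtype=float)
    if totals.size != successes.size or totals.size < 2:
        raise ParameterError("need >= 2 bins with matching totals/successes")
    if np.any(successes < 0) or np.any(successes > totals):
        raise ParameterError("successes must lie in [0, total] per bin")
    if scores is None:
        scores = np.arange(totals.size, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = totals.sum()
    pbar = successes.sum() / n
    if pbar == 0 or pbar == 1:
        return 0.0, 1.0
    num = float((scores * (successes - totals * pbar)).sum()) ** 2
    den = pbar * (1 - pbar) * (
        float((totals * scores**2).sum()) - float((totals * scores).sum()) ** 2 / n
    )
    if den == 0:
        return 0.0, 1.0
    chi2 = num / den
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def chisq_independence(
    table: Contingency2x2 | np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """1-df chi-square test of independence on a 2x2 table."""
    arr = table.as_array() if isinstance(table, Contingency2x2) else np.asarray(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise UndefinedStatisticError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


def window_track_correlation(
    a,
    b,
    mask=None,
    stratify_by=None,
    min_stratum: int = 3,
):
    """Pearson correlation between two per-window tracks.

    With ``stratify_by`` (per-window integer, e.g. GC count), one
    correlation plus a Fisher-z 95% CI is computed per stratum with at
    least ``min_stratum`` windows; smaller strata are skipped and
    flagged.  Returns a float, or a DataFrame when stratified.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must have equal length")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
        if stratify_by is not None:
            stratify_by = np.asarray(stratify_by)[mask]
    if stratify_by is None:
        if a.size < 3:
            raise UndefinedStatisticError("need >= 3 windows")
        return float(stats.pearsonr(a, b).statistic)
    stratify_by = np.asarray(stratify_by)
    rows = []
    for val in np.unique(stratify_by):
        sel = stratify_by == val
        n = int(sel.sum())
        if n < min_stratum or np.std(a[sel]) == 0 or np.std(b[sel]) == 0:
            rows.append(
                {"stratum": val, "n": n, "r": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "skipped": True}
            )
            continue
        r = float(stats.pearsonr(a[sel], b[sel]).statistic)
        if n > 3 and abs(r) < 1:
            z = np.arctanh(r)
            se = 1 / np.sqrt(n - 3)
            lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
        else:
            lo = hi = np.nan
        rows.append(
            {"stratum": val, "n": n, "r": r,
             "ci_low": float(lo), "ci_high": float(hi), "skipped": False}
        )
    return pd.DataFrame(rows)


def genic_window_mask(grid, genes, upstream_bp: int = 1000) -> np.ndarray:
    """True for windows intersecting a gene span or 1 kb upstream of a TSS.

    Used to split ROC analyses into genic / non-genic fractions.
    """
    mask = np.zeros(grid.n_windows, dtype=bool)
    for g in genes:
        try:
            ci = grid.chrom_index(g.chrom)
        except KeyError:
            continue
        lo, hi = g.span
        if g.strand == "+":
            lo = max(0, lo - upstream_bp)
        else:
            hi = hi + upstream_bp
        first = max(0, lo // grid.width)
        last = min(int(grid.counts[ci]) - 1, (hi - 1) // grid.width)
        if last >= first:
            fl = int(grid.offsets[ci])
            mask[fl + first : fl + last + 1] = True
    return mask


def windows_overlapping_regions(grid, regions: pd.DataFrame) -> np.ndarray:
    """Boolean per-window label: intersects any region by >= 1 bp."""
    mask = np.zeros(grid.n_windows, dtype=bool)
    w = grid.width
    for row in regions.itertuples(index=False):
        try:
            ci = grid.chrom_index(row.chrom)
        except KeyError:
            continue
        first = max(0, int(row.start) // w)
        last = min(int(grid.counts[ci]) - 1, (int(row.end) - 1) // w)
        if last >= first:
            fl = int(grid.offsets[ci])
            mask[fl + first : fl + last + 1] = True
    return mask
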