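"""Synthetic genomes, reads, and annotations for end-to-end testing.

The generator plants the statistical structure the analysis assumes:

* a background genome with configurable GC content and CpG depletion
  (a fraction of background CG dinucleotides is rewritten, emulating
  methylation-driven CpG loss);
* class-specific promoter architecture — sharp GC-rich CpG-island
  blocks at housekeeping TSSs, broad GC-rich domains at developmental
  regulators, AT-rich promoters at tissue-specific genes;
* nucleosome-fraction reads whose window sampling weight grows with GC
  (strength ``beta``) and input reads with a mild GC bias (``gamma``);
* a 10-tissue RPKM matrix, 13-donor presence calls, and island
  methylation labels correlated with retention overlap.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from nucret.genes import GeneModel
from nucret.seqcomp import Genome, ParameterError, WindowGrid, window_base_counts

TISSUES = (
    "testes", "brain", "breast", "colon", "heart",
    "liver", "lymph_node", "skeletal_muscle", "cerebellum", "kidney",
)

_DEV_GO = frozenset(
    {
        ("GO:0006355", "regulation of transcription, DNA-dependent"),
        ("GO:0009790", "embryo development"),
    }
)
_NEUTRAL_GO = (
    ("GO:0008152", "metabolic process"),
    ("GO:0006412", "translation"),
    ("GO:0006457", "protein folding"),
)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic generator; defaults run in well under 5 min."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_500_000, 2_500_000)
    background_gc: float = 0.40
    cpg_depletion: float = 0.80  # fraction of background CGs rewritten

    n_housekeeping: int = 120
    n_tissue_specific: int = 90
    n_dev_tf: int = 30
    n_other: int = 60
    gene_length_bp: int = 2_000
    hk_island_bp: int = 600
    hk_island_gc: float = 0.72
    dev_block_bp: int = 4_000
    dev_block_gc: float = 0.65
    ts_promoter_bp: int = 1_000
    ts_promoter_gc: float = 0.30

    beta: float = 4.0    # GC -> nucleosome sampling coupling
    gamma: float = 0.5   # mild GC bias of the input library
    nuc_depth: int = 500_000
    input_depth: int = 500_000
    window_bp: int = 150
    shift_bp: int = 75

    p_unmeth_given_retained: float = 0.90
    p_unmeth_given_not: float = 0.15
    sperm_present_fraction: float = 0.60
    n_donors: int = 13
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self) -> None:
        if any(ln < 10_000 for ln in self.chrom_lengths):
            raise ParameterError("chromosome lengths must be >= 10 kb")
        for name in ("background_gc", "cpg_depletion", "hk_island_gc",
                     "dev_block_gc", "ts_promoter_gc",
                     "p_unmeth_given_retained", "p_unmeth_given_not",
                     "sperm_present_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.nuc_depth <= 0 or self.input_depth <= 0:
            raise ParameterError("library depths must be positive")
        if self.beta < 0 or self.gamma < 0:
            raise ParameterError("coupling strengths must be >= 0")

    @property
    def n_genes(self) -> int:
        return (self.n_housekeeping + self.n_tissue_specific
                + self.n_dev_tf + self.n_other)

    def to_dict(self) -> dict:
        return asdict(self)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Per-base codes (0=A,1=C,2=G,3=T) drawn iid at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _deplete_cpg(rng: np.random.Generator, codes: np.ndarray, frac: float) -> None:
    """Rewrite a fraction of CG dinucleotides in place (C->T or G->A)."""
    if frac <= 0:
        return
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
    hit = cg[rng.random(cg.size) < frac]
    to_t = rng.random(hit.size) < 0.5
    codes[hit[to_t]] = 3       # C -> T
    codes[hit[~to_t] + 1] = 0  # G -> A


_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def generate_genome(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[Genome, list[GeneModel], dict[str, str]]:
    """Background genome plus planted genes with class-specific promoters.

    Returns (genome, gene models, gene_id -> class label).  Gene slots
    are evenly spaced so genes and their promoter blocks never overlap;
    a config whose genes do not fit raises a parameter error.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_genes = config.n_genes
    slot_bp = (config.gene_length_bp
               + max(config.hk_island_bp, config.dev_block_bp,
                     config.ts_promoter_bp) + 2_000)
    total_bp = sum(config.chrom_lengths)
    if n_genes * slot_bp > total_bp:
        raise ParameterError(
            f"{n_genes} genes x {slot_bp} bp slots exceed the genome"
        )

    chrom_codes = {}
    for k, length in enumerate(config.chrom_lengths):
        codes = _random_bases(rng, length, config.background_gc)
        _deplete_cpg(rng, codes, config.cpg_depletion)
        chrom_codes[f"chr{k + 1}"] = codes

    labels = (
        ["housekeeping"] * config.n_housekeeping
        + ["tissue_specific"] * config.n_tissue_specific
        + ["developmental_TF"] * config.n_dev_tf
        + ["other"] * config.n_other
    )
    rng.shuffle(labels)

    # distribute slots over chromosomes proportionally to length
    names = list(chrom_codes)
    alloc = [round(n_genes * ln / total_bp) for ln in config.chrom_lengths]
    while sum(alloc) > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_genes:
        alloc[int(np.argmin(alloc))] += 1

    block_bp = {
        "housekeeping": (config.hk_island_bp, config.hk_island_gc),
        "developmental_TF": (config.dev_block_bp, config.dev_block_gc),
        "tissue_specific": (config.ts_promoter_bp, config.ts_promoter_gc),
    }
    genes: list[GeneModel] = []
    class_of: dict[str, str] = {}
    li = 0
    for name, count in zip(names, alloc):
        codes = chrom_codes[name]
        length = codes.size
        if count == 0:
            continue
        # evenly spaced slot centers, away from the chromosome ends
        centers = np.linspace(slot_bp, length - slot_bp, count).astype(np.int64)
        for pos in centers:
            label = labels[li]
            gid = f"G{li:04d}"
            li += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int(pos)
            tes = tss + config.gene_length_bp if strand == "+" else tss - config.gene_length_bp
            if label in block_bp:
                blk, gc = block_bp[label]
                lo = max(0, tss - blk // 2)
                hi = min(length, tss + blk - blk // 2)
                codes[lo:hi] = _random_bases(rng, hi - lo, gc)
            go: set[tuple[str, str]] = set()
            if label == "developmental_TF":
                go |= _DEV_GO
            elif rng.random() < 0.3:
                go.add(_NEUTRAL_GO[int(rng.integers(len(_NEUTRAL_GO)))])
            tx = [tss]
            if rng.random() < 0.2:  # occasional alternative start
                tx.append(tss + int(rng.integers(50, 400)) * (1 if strand == "+" else -1))
            genes.append(GeneModel(gid, name, strand, tss, tes, tx, go))
            class_of[gid] = label

    genome = Genome({name: _codes_to_str(c) for name, c in chrom_codes.items()})
    return genome, genes, class_of


def simulate_reads(
    genome: Genome, config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw nucleosome and input 5'-end read tables over the window grid.

    Window sampling weight is proportional to exp(strength * gc_fraction)
    with strength ``beta`` for the nucleosome library and ``gamma`` for
    the input.  Centers are uniform within the window; reads are emitted
    at ``center -/+ shift_bp`` with a random strand, so shifting them
    back recovers the sampled centers exactly.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    grid = WindowGrid.from_genome(genome, config.window_bp)
    comp = window_base_counts(genome, grid)
    gc_frac = comp.gc_fraction
    bounds = grid.window_bounds()
    starts = bounds["start"].to_numpy(np.int64)
    chroms = bounds["chrom"].to_numpy()
    lengths = {c: genome.length(c) for c in genome.names}

    def draw(depth: int, strength: float) -> pd.DataFrame:
        w = np.exp(strength * gc_frac)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ParameterError("zero or invalid total sampling weight")
        p = w / total
        out_chrom: list[np.ndarray] = []
        out_five: list[np.ndarray] = []
        out_strand: list[np.ndarray] = []
        need = depth
        while need > 0:
            counts = rng.multinomial(need, p)
            idx = np.repeat(np.arange(grid.n_windows), counts)
            centers = starts[idx] + rng.integers(0, grid.width, size=idx.size)
            plus = rng.random(idx.size) < 0.5
            five = np.where(plus, centers - config.shift_bp,
                            centers + config.shift_bp)
            chrom = chroms[idx]
            ln = np.array([lengths[c] for c in grid.chrom_names])
            chrom_len = ln[np.searchsorted(grid.offsets, idx, side="right") - 1]
            ok = (five >= 0) & (five < chrom_len)
            out_chrom.append(chrom[ok])
            out_five.append(five[ok])
            out_strand.append(np.where(plus[ok], "+", "-"))
            need = depth - sum(a.size for a in out_five)
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(out_chrom),
                "five_prime": np.concatenate(out_five).astype(np.int64),
                "strand": np.concatenate(out_strand),
            }
        )
        return df.iloc[:depth].reset_index(drop=True)

    nuc = draw(config.nuc_depth, config.beta)
    inp = draw(config.input_depth, config.gamma)
    return nuc, inp


def simulate_labels(
    islands: pd.DataFrame,
    regions: pd.DataFrame,
    class_of: dict[str, str],
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Methylation labels, a 10-tissue RPKM matrix, and 13-donor calls.

    Island methylation is Bernoulli conditioned on overlap with a
    retention region; housekeeping genes get RPKM >= 0.5 in every
    tissue, tissue-specific genes in exactly one.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)

    by_chrom = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )

    def overlaps(chrom, start, end) -> bool:
        if chrom not in by_chrom:
            return False
        s, e = by_chrom[chrom]
        k = np.searchsorted(s, end)
        return bool((e[:k] > start).any())

    islands = islands.copy()
    ov = np.array(
        [overlaps(r.chrom, r.start, r.end) for r in islands.itertuples(index=False)]
    )
    p = np.where(ov, config.p_unmeth_given_retained, config.p_unmeth_given_not)
    islands["retained"] = ov
    islands["unmethylated"] = rng.random(len(islands)) < p

    gene_ids = sorted(class_of)
    nt = len(config.tissues)
    rpkm = np.empty((len(gene_ids), nt))
    for r, gid in enumerate(gene_ids):
        label = class_of[gid]
        if label == "housekeeping":
            rpkm[r] = 0.5 + rng.lognormal(1.0, 1.0, nt)
        elif label == "tissue_specific":
            row = rng.uniform(0.0, 0.49, nt)
            row[int(rng.integers(nt))] = 0.5 + rng.lognormal(0.5, 1.0)
            rpkm[r] = row
        else:
            expressed = rng.random(nt) < 0.6
            row = np.where(
                expressed, 0.5 + rng.lognormal(0.5, 1.0, nt),
                rng.uniform(0.0, 0.49, nt),
            )
            if label == "developmental_TF" and not expressed.any():
                row[int(rng.integers(nt))] = 0.6
            rpkm[r] = row
    rpkm_df = pd.DataFrame(rpkm, index=pd.Index(gene_ids, name="gene_id"),
                           columns=list(config.tissues))

    present = rng.random(len(gene_ids)) < config.sperm_present_fraction
    p_call = np.where(present, 0.8, 0.2)
    calls = rng.random((len(gene_ids), config.n_donors)) < p_call[:, None]
    calls_df = pd.DataFrame(
        calls,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"donor{d + 1}" for d in range(config.n_donors)],
    )
    return islands, rpkm_df, calls_df


def write_expression_tsv(rpkm: pd.DataFrame, path) -> None:
    rpkm.to_csv(path, sep="\t")


def write_presence_tsv(calls: pd.DataFrame, path) -> None:
    calls.replace({True: "P", False: "A"}).to_csv(path, sep="\t")


def read_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    return df == "P"
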