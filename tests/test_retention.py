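"""Read shifting, center counting, subsampling, scores, and region calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nucret.retention import (
    ReadRecord,
    RetentionParams,
    binomial_enrichment_score,
    call_enriched_regions,
    count_centers_in_windows,
    dedup_reads,
    low_coverage_filter,
    normalized_retention_score,
    reads_from_bed6,
    shift_read_to_center,
    shift_reads,
    subsample_reads,
)
from nucret.seqcomp import Genome, ParameterError, make_windows


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "five_prime", "strand"])


class TestShift:
    def test_plus_strand(self):
        assert shift_read_to_center(ReadRecord("c", 1000, "+"), 75) == 1075

    def test_minus_strand(self):
        assert shift_read_to_center(ReadRecord("c", 1000, "-"), 75) == 925

    def test_negative_center_dropped_by_counter(self):
        g = Genome({"c": "A" * 300})
        grid = make_windows(g, 150)
        counts = count_centers_in_windows(
            reads_df([("c", 30, "-")]), grid, shift_bp=75
        )
        assert counts.sum() == 0

    def test_vectorized_matches_scalar(self, rng):
        df = reads_df(
            [("c", int(p), s) for p, s in
             zip(rng.integers(0, 10_000, 100),
                 rng.choice(["+", "-"], 100))]
        )
        expect = [
            shift_read_to_center(ReadRecord(*row), 75)
            for row in df.itertuples(index=False)
        ]
        assert (shift_reads(df, 75) == expect).all()


class TestCountCenters:
    def test_half_open_boundaries(self):
        g = Genome({"c": "A" * 300})
        grid = make_windows(g, 150)
        # centers at 10, 149, 160 (shift 0 for directness)
        counts = count_centers_in_windows(
            reads_df([("c", 10, "+"), ("c", 149, "+"), ("c", 160, "+")]),
            grid, shift_bp=0,
        )
        assert list(counts) == [2, 1]

    def test_center_exactly_at_window_boundary(self):
        g = Genome({"c": "A" * 300})
        grid = make_windows(g, 150)
        counts = count_centers_in_windows(
            reads_df([("c", 150, "+")]), grid, shift_bp=0
        )
        assert list(counts) == [0, 1]

    def test_conservation(self, rng):
        g = Genome({"c": "A" * 150_000})
        grid = make_windows(g, 150)
        pos = rng.integers(100, 149_000, size=1000)
        df = reads_df([("c", int(p), "+") for p in pos])
        assert count_centers_in_windows(df, grid, shift_bp=75).sum() == 1000

    def test_unknown_chromosome_skipped(self, caplog):
        g = Genome({"c": "A" * 300})
        grid = make_windows(g, 150)
        with caplog.at_level("WARNING"):
            counts = count_centers_in_windows(
                reads_df([("nope", 10, "+")]), grid, shift_bp=0
            )
        assert counts.sum() == 0
        assert "unknown chromosome" in caplog.text

    def test_dedup_collapses_identical_records(self):
        g = Genome({"c": "A" * 300})
        grid = make_windows(g, 150)
        df = reads_df([("c", 10, "+")] * 5 + [("c", 10, "-")])
        assert count_centers_in_windows(df, grid, 0, dedup=True).sum() == 2
        assert count_centers_in_windows(df, grid, 0, dedup=False).sum() == 6
        assert len(dedup_reads(df)) == 2


class TestReadsIO:
    def test_bed6_minus_strand_five_prime(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("c\t100\t136\tr1\t0\t+\nc\t100\t136\tr2\t0\t-\n")
        df = reads_from_bed6(path)
        assert list(df["five_prime"]) == [100, 135]


class TestSubsample:
    def test_full_sample_is_identity(self, rng):
        df = reads_df([("c", int(p), "+") for p in rng.integers(0, 1000, 50)])
        out = subsample_reads(df, 50, seed=1)
        pd.testing.assert_frame_equal(out, df.reset_index(drop=True))

    def test_deterministic(self, rng):
        df = reads_df([("c", int(p), "+") for p in rng.integers(0, 1000, 500)])
        a = subsample_reads(df, 100, seed=7)
        b = subsample_reads(df, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_target_exceeds_total(self):
        df = reads_df([("c", 1, "+")])
        with pytest.raises(ParameterError):
            subsample_reads(df, 2, seed=0)

    def test_exact_count_and_subset(self, rng):
        df = reads_df(
            [("c", int(p), "+") for p in rng.integers(0, 10_000, 300)]
        )
        out = subsample_reads(df, 120, seed=3)
        assert len(out) == 120
        merged = out.merge(df.drop_duplicates(), on=list(df.columns))
        assert len(merged) >= 120  # every sampled read exists in the source

    def test_hypergeometric_window_means(self):
        """Per-window retained counts average to original * target/total."""
        g = Genome({"c": "A" * 3000})
        grid = make_windows(g, 150)
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 3000, size=2000)
        df = reads_df([("c", int(p), "+") for p in pos])
        base = count_centers_in_windows(df, grid, shift_bp=0)
        target = 500
        acc = np.zeros(grid.n_windows)
        n_seeds = 200
        for seed in range(n_seeds):
            sub = subsample_reads(df, target, seed=seed)
            acc += count_centers_in_windows(sub, grid, shift_bp=0)
        mean = acc / n_seeds
        expect = base * target / len(df)
        # Monte-Carlo error: sd of hypergeometric mean over 200 seeds
        frac = target / len(df)
        sd = np.sqrt(base * frac * (1 - frac) / n_seeds) + 1e-9
        assert (np.abs(mean - expect) < 5 * sd + 0.05).all()
        assert acc.sum() == n_seeds * target  # totals conserved exactly


class TestNormalizedScore:
    def test_symmetry_zero(self):
        assert normalized_retention_score(7, 7) == 0.0

    def test_hand_values(self):
        assert normalized_retention_score(9, 4) == pytest.approx(1.386750490563073)
        assert normalized_retention_score(0, 9) == pytest.approx(-3.0)

    def test_undefined_at_zero_total(self):
        with pytest.raises(ParameterError):
            normalized_retention_score(0, 0)

    @given(n=st.integers(0, 500), i=st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, n, i):
        if n + i == 0:
            return
        assert normalized_retention_score(n, i) == pytest.approx(
            -normalized_retention_score(i, n)
        )

    def test_null_mean_near_zero_at_depth(self, rng):
        n = rng.poisson(20, size=100_000)
        i = rng.poisson(20, size=100_000)
        ok = (n + i) > 0
        scores = normalized_retention_score(n[ok], i[ok])
        assert abs(scores.mean()) < 0.05


class TestLowCoverageFilter:
    @pytest.mark.parametrize(
        "n,i,kept", [(3, 1, False), (3, 2, True), (0, 5, True)]
    )
    def test_boundary(self, n, i, kept):
        assert low_coverage_filter(np.array([n]), np.array([i]))[0] == kept


class TestBinomialEnrichment:
    def test_zero_signal(self):
        assert binomial_enrichment_score(0, 10, 0.5) == 0.0

    def test_derived_tail(self):
        # P(Bin(10, .5) >= 8) = 56/1024 = 0.0546875
        assert binomial_enrichment_score(8, 2, 0.5) == pytest.approx(
            1.2621119296336112
        )

    def test_null_expectation_near_zero(self):
        # signal at its expectation: tail prob ~ 0.5, score ~ 0.3
        assert binomial_enrichment_score(50, 50, 0.5) < 0.5

    def test_invalid_depth_ratio(self):
        with pytest.raises(ParameterError):
            binomial_enrichment_score(1, 1, 1.5)


def uniform_reads(rng, length, n, chrom="c"):
    pos = rng.integers(75, length - 76, size=n)
    strand = rng.choice(["+", "-"], size=n)
    return pd.DataFrame({"chrom": chrom, "five_prime": pos, "strand": strand})


class TestCallEnrichedRegions:
    def test_single_hotspot(self, rng):
        length = 30_000
        g = Genome({"c": "A" * length})
        # all nucleosome fragment centers inside [9000, 9300)
        centers = rng.integers(9000, 9300, size=2000)
        strand = rng.choice(["+", "-"], size=2000)
        five = np.where(strand == "+", centers - 75, centers + 75)
        nuc = pd.DataFrame({"chrom": "c", "five_prime": five, "strand": strand})
        inp = uniform_reads(rng, length, 2000)
        out = call_enriched_regions(nuc, inp, g)
        assert len(out) == 1
        assert out.loc[0, "start"] <= 9000 and out.loc[0, "end"] >= 9300
        assert out.loc[0, "enrichment_score"] > 10

    def test_null_no_regions(self, rng):
        length = 50_000
        g = Genome({"c": "A" * length})
        reads = uniform_reads(rng, length, 5000)
        out = call_enriched_regions(reads.copy(), reads.copy(), g)
        assert len(out) == 0

    def test_two_separated_hotspots(self, rng):
        length = 60_000
        g = Genome({"c": "A" * length})
        c1 = rng.integers(10_000, 10_300, size=1000)
        c2 = rng.integers(40_000, 40_300, size=1000)
        centers = np.concatenate([c1, c2])
        strand = rng.choice(["+", "-"], size=2000)
        five = np.where(strand == "+", centers - 75, centers + 75)
        nuc = pd.DataFrame({"chrom": "c", "five_prime": five, "strand": strand})
        inp = uniform_reads(rng, length, 2000)
        out = call_enriched_regions(nuc, inp, g)
        assert len(out) == 2
        assert out.loc[0, "end"] <= 11_000 and out.loc[1, "start"] >= 39_000

    def test_one_sided(self, rng):
        """Label-swapped inputs never reproduce the forward region set."""
        length = 40_000
        g = Genome({"c": "A" * length})
        centers = rng.integers(5000, 5300, size=1500)
        strand = rng.choice(["+", "-"], size=1500)
        five = np.where(strand == "+", centers - 75, centers + 75)
        nuc = pd.DataFrame({"chrom": "c", "five_prime": five, "strand": strand})
        inp = uniform_reads(rng, length, 1500)
        fwd = call_enriched_regions(nuc, inp, g)
        rev = call_enriched_regions(inp, nuc, g)
        assert len(fwd) == 1
        fwd_set = set(map(tuple, fwd[["chrom", "start", "end"]].to_numpy()))
        rev_set = set(map(tuple, rev[["chrom", "start", "end"]].to_numpy()))
        assert not (fwd_set and fwd_set == rev_set)

    def test_hotspot_binomial_tail_is_significant(self):
        """The caller's test matches a directly computed binomial tail."""
        # 300-bp window: nuc 100 of 1000 total reads in window vs
        # depth_ratio 0.5 -> astronomically significant
        p = stats.binom.sf(99, 120, 0.5)
        assert -np.log10(p) > 10

    def test_empty_reads_error(self, rng):
        g = Genome({"c": "A" * 1000})
        df = uniform_reads(rng, 1000, 10)
        with pytest.raises(ParameterError):
            call_enriched_regions(df.iloc[:0], df, g)


class TestRetentionParams:
    def test_defaults(self):
        p = RetentionParams()
        assert (p.shift_bp, p.window_bp, p.min_total_reads,
                p.caller_window_bp) == (75, 150, 5, 300)

    def test_validation(self):
        with pytest.raises(ParameterError):
            RetentionParams(shift_bp=0)
        with pytest.raises(ParameterError):
            RetentionParams(caller_alpha=1.5)
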