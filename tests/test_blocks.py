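"""D' confidence intervals, pair classification and block assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapharm.blocks import (
    STRONG_LD,
    STRONG_RECOMB,
    UNINFORMATIVE,
    LinkageBlockDef,
    MonomorphicPairError,
    SnpRecord,
    classify_pair,
    detect_blocks,
    find_blocks,
    pair_dprime_ci,
    read_plink_blocks,
    write_plink_blocks,
)
from hapharm.simulate import SimConfig, simulate_dataset


def oracle_dprime_ci(counts, grid_step=0.001, ci_mass=0.90):
    """Independent likelihood-grid evaluation (scalar loop, no shortcuts)."""
    import math

    n_ab, n_aB, n_Ab, n_AB = counts[3], counts[2], counts[1], counts[0]
    n = n_AB + n_Ab + n_aB + n_ab
    pa = (n_AB + n_Ab) / n
    pb = (n_AB + n_aB) / n
    d = n_AB / n - pa * pb
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if d >= 0 else min(pa * pb, (1 - pa) * (1 - pb))
    sign = 1 if d >= 0 else -1
    grid, logl = [], []
    g = 0.0
    while g <= 1.0 + 1e-12:
        dd = sign * g * dmax
        f = [pa * pb + dd, pa * (1 - pb) - dd, (1 - pa) * pb - dd,
             (1 - pa) * (1 - pb) + dd]
        ll = 0.0
        for cnt, fr in zip((n_AB, n_Ab, n_aB, n_ab), f):
            if cnt > 0:
                ll += cnt * math.log(fr) if fr > 0 else -math.inf
        grid.append(round(g, 6))
        logl.append(ll)
        g += grid_step
    m = max(logl)
    lik = [math.exp(v - m) for v in logl]
    s = sum(lik)
    cum, acc = [], 0.0
    for v in lik:
        acc += v / s
        cum.append(acc)
    lo_t = (1 - ci_mass) / 2
    hi_t = 1 - lo_t
    lo = next(g for g, c in zip(grid, cum) if c >= lo_t)
    hi = next(g for g, c in zip(grid, cum) if c >= hi_t)
    return abs(d) / dmax if dmax > 0 else 0.0, lo, hi


class TestPairDprimeCI:
    def test_perfect_ld_large_sample(self):
        dp, lo, hi = pair_dprime_ci((50, 0, 0, 50))
        assert dp == pytest.approx(1.0)
        assert lo > 0.9

    def test_independence_gives_zero_dprime(self):
        dp, _, _ = pair_dprime_ci((25, 25, 25, 25))
        assert dp == pytest.approx(0.0, abs=1e-12)

    def test_tiny_sample_gives_wide_interval(self):
        dp, lo, _ = pair_dprime_ci((1, 0, 0, 1))
        assert dp == pytest.approx(1.0)
        assert lo < 0.7

    @pytest.mark.parametrize(
        "counts",
        [(50, 0, 0, 50), (1, 0, 0, 1), (30, 5, 5, 30), (10, 20, 30, 40),
         (7, 1, 2, 9)],
    )
    def test_matches_independent_grid_oracle(self, counts):
        got = pair_dprime_ci(counts)
        exp = oracle_dprime_ci(counts)
        assert got[0] == pytest.approx(exp[0], abs=1e-9)
        assert got[1] == pytest.approx(exp[1], abs=1e-6)
        assert got[2] == pytest.approx(exp[2], abs=1e-6)

    def test_monomorphic_pair_is_flagged(self):
        with pytest.raises(MonomorphicPairError):
            pair_dprime_ci((50, 50, 0, 0))

    def test_bounds_bracket_estimate_order(self):
        _, lo, hi = pair_dprime_ci((40, 3, 2, 41))
        assert 0 <= lo <= hi <= 1


class TestClassifyPair:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.75, 0.99, STRONG_LD),
            (0.10, 0.85, STRONG_RECOMB),
            (0.50, 0.95, UNINFORMATIVE),
            (0.70, 0.98, STRONG_LD),   # thresholds inclusive
            (0.69, 0.99, UNINFORMATIVE),
        ],
    )
    def test_rules(self, lo, hi, expected):
        assert classify_pair(lo, hi) == expected

    @given(
        lo=st.floats(0, 1), hi=st.floats(0, 1),
        dlo=st.floats(0, 0.5), dhi=st.floats(0, 0.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_bounds(self, lo, hi, dlo, dhi):
        """Raising either bound never demotes strong LD to recombination."""
        if lo > hi:
            lo, hi = hi, lo
        hi2 = min(hi + dhi, 1.0)
        lo2 = min(lo + dlo, hi2)
        before = classify_pair(lo, hi)
        after = classify_pair(lo2, hi2)
        if before == STRONG_LD:
            assert after != STRONG_RECOMB
        if before == UNINFORMATIVE:
            assert after != STRONG_RECOMB


def _snps(positions, chrom="1"):
    return [SnpRecord(chrom, p, f"s{k}") for k, p in enumerate(positions)]


def _perfect_ld_haps(n_hap, n_snps, rng):
    """Half the chromosomes all-0, half all-1 at every SNP: |D'| = 1."""
    hap = np.zeros((n_hap, n_snps), dtype=np.uint8)
    hap[rng.permutation(n_hap)[: n_hap // 2]] = 1
    return hap


class TestFindBlocks:
    def test_perfect_ld_cluster_is_one_block(self):
        rng = np.random.default_rng(0)
        snps = _snps([1000, 3000, 5000, 8000, 11000])
        hap = _perfect_ld_haps(200, 5, rng)
        blocks = detect_blocks(hap, snps)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == (0, 1, 2, 3, 4)

    def test_distant_clusters_never_merge(self):
        rng = np.random.default_rng(1)
        snps = _snps([1000, 2000, 501000, 502000])
        left = _perfect_ld_haps(200, 2, rng)
        right = _perfect_ld_haps(200, 2, rng)
        hap = np.hstack([left, right])
        blocks = detect_blocks(hap, snps)
        assert len(blocks) == 2
        assert blocks[0].snp_indices == (0, 1)
        assert blocks[1].snp_indices == (2, 3)

    def test_independent_snps_give_no_blocks(self):
        rng = np.random.default_rng(2)
        snps = _snps([1000, 2000, 3000, 4000])
        hap = rng.integers(0, 2, size=(400, 4), dtype=np.uint8)
        assert detect_blocks(hap, snps) == []

    def test_spans_respect_cap(self, clean_ds):
        blocks = detect_blocks(clean_ds.haplotypes, clean_ds.snps)
        assert all(b.length_bp <= 400_000 for b in blocks)

    def test_recovers_planted_boundaries(self):
        cfg = SimConfig(seed=3, n_founders=20, n_generations=2,
                        families_per_generation=8, offspring_range=(5, 9),
                        n_blocks=5, snps_per_block=(4, 8),
                        founder_haplotypes_per_block=(2, 2),
                        complementary_pools=True)
        ds = simulate_dataset(cfg)
        found = detect_blocks(ds.haplotypes, ds.snps)
        assert [(b.chrom, b.start_bp, b.end_bp) for b in found] == \
            [(b.chrom, b.start_bp, b.end_bp) for b in ds.blocks]


class TestBlockDefInvariants:
    def test_length_is_end_minus_start(self):
        blk = LinkageBlockDef("LBx", "13", 100, 350, (0, 1))
        assert blk.length_bp == 250

    def test_reversed_coordinates_rejected(self):
        with pytest.raises(ValueError):
            LinkageBlockDef("LBx", "1", 200, 100)


class TestPlinkBlocksIO:
    def test_single_row(self, tmp_path):
        snps = _snps([100, 200, 300])
        path = tmp_path / "b.blocks.det"
        path.write_text("CHR BP1 BP2 KB NSNPS SNPS\n1 100 300 0.2 3 s0|s1|s2\n")
        blocks = read_plink_blocks(path, snps)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == (0, 1, 2)

    def test_unknown_snp_skips_block_with_warning(self, tmp_path):
        snps = _snps([100, 200])
        path = tmp_path / "b.blocks.det"
        path.write_text("CHR BP1 BP2 KB NSNPS SNPS\n1 100 200 0.1 2 s0|nope\n")
        with pytest.warns(UserWarning, match="unknown SNP"):
            assert read_plink_blocks(path, snps) == []

    def test_malformed_row_is_fatal(self, tmp_path):
        snps = _snps([100, 200])
        path = tmp_path / "b.blocks.det"
        path.write_text("CHR BP1 BP2 KB NSNPS SNPS\n1 100\n")
        with pytest.raises(ValueError, match="malformed"):
            read_plink_blocks(path, snps)

    def test_round_trip(self, tmp_path):
        snps = _snps([100, 200, 300, 5000])
        blocks = [
            LinkageBlockDef("LB1", "1", 100, 300, (0, 1, 2)),
            LinkageBlockDef("LB2", "1", 300, 5000, (2, 3)),
        ]
        path = tmp_path / "rt.blocks.det"
        write_plink_blocks(blocks, snps, path)
        back = read_plink_blocks(path, snps)
        assert [(b.chrom, b.start_bp, b.end_bp, b.snp_indices) for b in back] \
            == [(b.chrom, b.start_bp, b.end_bp, b.snp_indices) for b in blocks]
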