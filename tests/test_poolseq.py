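"""Pool variant filtering, endemic classification, Fst and genome scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cottonwood.containers import PoolFrequencies
from cottonwood.poolseq import (
    PoolFilterRules,
    apply_detection_limit,
    classify_endemic,
    filter_pool_variants,
    fst_scan,
    one_vs_rest_fst,
    pairwise_fst_matrix,
    pool_fst,
)
from cottonwood.sim import DivergenceModelSpec, simulate_divergence_afs

POOLS = ["ne", "south", "admixed", "west"]


def variant_row(chrom="Chr01", pos=100, n_alleles=2, qual=30.0,
                covs=(300, 200, 450, 160), freqs=(0.3, 0.2, 0.4, 0.1),
                merged_cov=900, merged_freq=0.25):
    row = {"chrom": chrom, "pos": pos, "n_alleles": n_alleles, "qual": qual}
    for p, c, f in zip(POOLS, covs, freqs):
        row[f"cov_{p}"] = c
        row[f"freq_{p}"] = f
    row["cov_merged"] = merged_cov
    row["freq_merged"] = merged_freq
    return row


def make_pf(freqs, pools=None, chrom=None, pos=None, pool_size=20):
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    pools = pools or [f"P{j}" for j in range(freqs.shape[1])]
    idx = pd.Index([f"s{i}" for i in range(freqs.shape[0])])
    f = pd.DataFrame(freqs, index=idx, columns=pools)
    cov = pd.DataFrame(300, index=idx, columns=pools)
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else "Chr01",
            "pos": pos if pos is not None else np.arange(1, len(idx) + 1),
        },
        index=idx,
    )
    return PoolFrequencies(f, cov, snps, pd.Series(pool_size, index=pools))


class TestFilter:
    def test_every_rule_drops_its_snp_and_good_snp_survives(self):
        rows = [
            variant_row(pos=1),                                  # survives
            variant_row(pos=2, covs=(149, 200, 450, 160)),       # low pool cov
            variant_row(pos=3, covs=(300, 200, 501, 160)),       # high pool cov
            variant_row(pos=4, n_alleles=3),                     # triallelic
            variant_row(pos=5, qual=19.9),                       # low quality
            variant_row(pos=6, chrom="scaffold_123"),            # off-chromosome
            variant_row(pos=7, merged_cov=199),                  # thin merged pool
        ]
        pf, rejected = filter_pool_variants(pd.DataFrame(rows), POOLS, 20)
        assert pf.n_snps == 1
        assert int(pf.snps["pos"].iloc[0]) == 1
        expected = {
            "pool_coverage": 2,
            "not_biallelic": 1,
            "low_quality": 1,
            "not_on_chromosome": 1,
            "merged_pool": 1,
        }
        assert rejected.to_dict() == expected

    def test_coverage_bounds_inclusive(self):
        rows = [
            variant_row(pos=1, covs=(150, 500, 150, 500)),
            variant_row(pos=2, covs=(150, 500, 150, 499)),
        ]
        pf, _ = filter_pool_variants(pd.DataFrame(rows), POOLS, 20)
        assert pf.n_snps == 2

    def test_missing_depth_column_errors(self):
        df = pd.DataFrame([variant_row()]).drop(columns=["cov_west"])
        with pytest.raises(ValueError, match="cov_west"):
            filter_pool_variants(df, POOLS, 20)


class TestDetectionLimit:
    def test_below_limit_zeroed_boundary_kept(self):
        pf = make_pf([[0.015, 0.020, 0.5]])
        out = apply_detection_limit(pf, 0.02)
        assert list(out.freqs.iloc[0]) == [0.0, 0.020, 0.5]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=8))
    def test_idempotent(self, freqs):
        pf = make_pf([freqs])
        once = apply_detection_limit(pf, 0.02)
        twice = apply_detection_limit(once, 0.02)
        pd.testing.assert_frame_equal(once.freqs, twice.freqs)


class TestEndemic:
    def test_categories(self):
        pf = make_pf(
            [
                [0.3, 0.0, 0.0, 0.0],   # endemic to pool 1
                [0.3, 0.2, 0.4, 0.1],   # polymorphic in all
                [0.0, 0.0, 0.0, 0.0],   # invariant
                [1.0, 1.0, 1.0, 1.0],   # invariant (fixed alt)
                [0.5, 0.5, 0.0, 1.0],   # shared subset
            ],
            pools=POOLS[:4],
        )
        res = classify_endemic(pf)
        assert list(res.categories) == [
            "endemic:ne", "polymorphic_in_all", "invariant", "invariant",
            "shared_subset",
        ]
        assert res.summary.loc["ne", "n_endemic"] == 1
        assert res.n_polymorphic_in_all == 1
        assert res.n_invariant == 2

    def test_excluding_admixed_pool_recounts(self):
        # polymorphic in 'south' and 'admixed' only: endemic to south once
        # the admixed pool is set aside
        pf = make_pf([[0.0, 0.3, 0.2, 0.0]], pools=POOLS)
        res = classify_endemic(pf, admixed_pool="admixed")
        assert res.summary.loc["south", "n_endemic"] == 0
        assert res.summary.loc["south", "n_endemic_excl_admixed"] == 1


class TestPoolFst:
    def test_fixed_difference_is_one(self):
        pf = make_pf([[0.0, 1.0]])
        assert pool_fst(pf, ("P0", "P1")).fst == pytest.approx(1.0)

    def test_hand_evaluated_toy_frequencies(self):
        # p = 0.2 vs 0.4: Hs = 0.40, Ht = 0.42, Fst = 0.02/0.42 = 1/21
        pf = make_pf([[0.2, 0.4]])
        res = pool_fst(pf, ("P0", "P1"))
        assert res.track["hs"].iloc[0] == pytest.approx(0.40)
        assert res.track["ht"].iloc[0] == pytest.approx(0.42)
        assert res.fst == pytest.approx(1 / 21, abs=1e-12)

    def test_monomorphic_snps_do_not_move_multilocus_fst(self):
        base = [[0.2, 0.4]]
        padded = base + [[0.0, 0.0]] * 1000
        a = pool_fst(make_pf(base), ("P0", "P1")).fst
        b = pool_fst(make_pf(padded), ("P0", "P1")).fst
        assert a == pytest.approx(b, abs=1e-15)

    def test_all_monomorphic_flagged_undefined(self):
        res = pool_fst(make_pf([[0.0, 0.0], [1.0, 1.0]]), ("P0", "P1"))
        assert res.undefined and np.isnan(res.fst)

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        pf = make_pf(rng.uniform(0, 1, size=(200, 4)), pools=POOLS)
        mat = pairwise_fst_matrix(pf)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_one_vs_rest_uses_mean_of_other_pools(self):
        pf = make_pf([[0.8, 0.1, 0.2, 0.3]], pools=POOLS)
        res = pool_fst(pf, "ne")
        rest = (0.1 + 0.2 + 0.3) / 3
        hs = (2 * 0.8 * 0.2 + 2 * rest * (1 - rest)) / 2
        pbar = (0.8 + rest) / 2
        ht = 2 * pbar * (1 - pbar)
        assert res.fst == pytest.approx((ht - hs) / ht)
        assert set(one_vs_rest_fst(pf).index) == set(POOLS)

    def test_fst_increases_with_divergence_time(self):
        vals = []
        for T in (50, 200, 800, 2000):
            spec = DivergenceModelSpec(model="isolation", Ne=500, T_split=T,
                                       n_loci=2000, seed=77)
            p1, p2 = simulate_divergence_afs(spec)
            pf = make_pf(np.column_stack([p1, p2]))
            vals.append(pool_fst(pf, ("P0", "P1")).fst)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_mean_he_equals_mean_2pq(self):
        rng = np.random.default_rng(9)
        f = rng.uniform(0, 1, 500)
        pf = make_pf(np.column_stack([f, f[::-1]]))
        mean_he = float(np.mean(2 * f * (1 - f)))
        per_pool = (pf.freqs["P0"] * (1 - pf.freqs["P0"]) * 2).mean()
        assert per_pool == pytest.approx(mean_he, abs=1e-12)


class TestScan:
    def _track(self, fst_by_pos, chrom="Chr01"):
        pos = np.array(sorted(fst_by_pos))
        return pd.DataFrame(
            {"chrom": chrom, "pos": pos, "fst": [fst_by_pos[p] for p in pos]}
        )

    def test_constant_track_has_no_peaks(self):
        track = self._track({p: 0.2 for p in range(1, 10_000_000, 50_000)})
        res = fst_scan(track, 500_000, min_snps=5, peak_quantile=0.99)
        assert len(res.peaks) == 0

    def test_planted_elevated_region_recovered_and_merged(self):
        rng = np.random.default_rng(15)
        pos = np.arange(1, 30_000_000, 25_000)
        fst = rng.uniform(0.03, 0.07, len(pos))
        plant = (pos >= 12_000_000) & (pos < 18_000_000)  # 6 Mb region
        fst[plant] = rng.uniform(0.7, 0.8, plant.sum())
        track = pd.DataFrame({"chrom": "Chr14", "pos": pos, "fst": fst})
        res = fst_scan(track, 500_000, min_snps=5, peak_quantile=0.8)
        assert len(res.peaks) == 1
        region = res.peaks.iloc[0]
        assert abs(region["start"] - 12_000_001) <= 500_000
        assert abs(region["end"] - 18_000_000) <= 500_000

    def test_single_window_mean_equals_chromosome_mean(self):
        track = self._track(
            {1_000: 0.1, 2_000: 0.2, 3_000: 0.3, 4_000: 0.4, 5_000: 0.5}
        )
        res = fst_scan(track, 10_000, min_snps=5, peak_quantile=0.99)
        assert len(res.windows) == 1
        assert res.windows["mean_fst"].iloc[0] == pytest.approx(0.3)
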