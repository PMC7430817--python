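"""Sync parsing, site classification, window scan, SDR calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan import poolscan, simdata
from sexscan.poolscan import (
    FEMALE_SPECIFIC,
    LOW_DEPTH,
    MALE_SPECIFIC,
    NONE,
    PoolScanParams,
    SDRPolicy,
    SyncRecord,
)

from conftest import brute_force_windows, make_balanced_truth

PARAMS = PoolScanParams()


class TestReadSync:
    def test_single_line(self):
        line = "LG22\t100\tA\t12:13:0:0:0:0\t30:0:0:0:0:0"
        (rec,) = list(poolscan.read_sync([line]))
        assert rec == SyncRecord(
            "LG22", 100, "A", (12, 13, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0)
        )

    def test_empty_stream(self):
        assert list(poolscan.read_sync([])) == []

    def test_three_pool_line_rejected(self):
        line = "LG1\t1\tA\t1:0:0:0:0:0\t1:0:0:0:0:0\t1:0:0:0:0:0"
        with pytest.raises(ValueError, match="line 1"):
            list(poolscan.read_sync([line]))

    def test_malformed_sextet_reports_line_number(self):
        lines = [
            "LG1\t1\tA\t1:0:0:0:0:0\t1:0:0:0:0:0",
            "LG1\t2\tA\t1:0:0:0\t1:0:0:0:0:0",
        ]
        with pytest.raises(ValueError, match="line 2"):
            list(poolscan.read_sync(lines))

    def test_out_of_order_positions_rejected(self):
        lines = [
            "LG1\t10\tA\t1:0:0:0:0:0\t1:0:0:0:0:0",
            "LG1\t5\tA\t1:0:0:0:0:0\t1:0:0:0:0:0",
        ]
        with pytest.raises(ValueError, match="out of order"):
            list(poolscan.read_sync(lines))


class TestParams:
    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            PoolScanParams(freq_het=0.5, range_het=0.5)
        with pytest.raises(ValueError):
            PoolScanParams(freq_hom=0.6, range_hom=0.2)
        with pytest.raises(ValueError):
            PoolScanParams(window_size=100, output_resolution=500)


def rec(male, female, chrom="LG1", pos=100, ref="A"):
    return SyncRecord(chrom, pos, ref, tuple(male), tuple(female))


class TestClassifySite:
    def test_male_heterozygous_female_fixed(self):
        # male 12A/13T (0.48/0.52), female fixed A
        r = rec((12, 13, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == MALE_SPECIFIC

    def test_low_depth(self):
        r = rec((5, 4, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == LOW_DEPTH

    def test_both_pools_fixed(self):
        r = rec((30, 0, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == NONE

    def test_n_and_del_excluded_from_depth(self):
        # nucleotide depth 9 despite 20 Ns
        r = rec((5, 4, 0, 0, 20, 0), (30, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == LOW_DEPTH

    def test_out_of_band_frequency_is_none(self):
        # male 0.25/0.75: outside 0.5 +/- 0.2
        r = rec((30, 10, 0, 0, 0, 0), (40, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == NONE

    def test_female_not_homozygous_enough_is_none(self):
        r = rec((12, 13, 0, 0, 0, 0), (28, 2, 0, 0, 0, 0))  # major 0.933 < 0.98
        assert poolscan.classify_site(r, PARAMS) == NONE

    def test_triallelic_male_pool_disqualified(self):
        r = rec((10, 10, 10, 0, 0, 0), (30, 0, 0, 0, 0, 0))
        assert poolscan.classify_site(r, PARAMS) == NONE

    def test_pool_swap_maps_male_to_female(self):
        r = rec((12, 13, 0, 0, 0, 0), (30, 0, 0, 0, 0, 0))
        swapped = rec(r.female, r.male)
        assert poolscan.classify_site(r, PARAMS) == MALE_SPECIFIC
        assert poolscan.classify_site(swapped, PARAMS) == FEMALE_SPECIFIC

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 60), min_size=4, max_size=4),
        st.lists(st.integers(0, 60), min_size=4, max_size=4),
        st.permutations(range(4)),
    )
    def test_consistent_base_relabelling_invariance(self, male, female, perm):
        r1 = rec((*male, 0, 0), (*female, 0, 0))
        male_p = [0] * 4
        female_p = [0] * 4
        for i, j in enumerate(perm):
            male_p[j] = male[i]
            female_p[j] = female[i]
        r2 = rec((*male_p, 0, 0), (*female_p, 0, 0))
        assert poolscan.classify_site(r1, PARAMS) == poolscan.classify_site(
            r2, PARAMS
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 60), min_size=4, max_size=4),
        st.lists(st.integers(0, 60), min_size=4, max_size=4),
    )
    def test_pool_swap_symmetry_property(self, male, female):
        r1 = rec((*male, 0, 0), (*female, 0, 0))
        r2 = rec((*female, 0, 0), (*male, 0, 0))
        mapping = {
            MALE_SPECIFIC: FEMALE_SPECIFIC,
            FEMALE_SPECIFIC: MALE_SPECIFIC,
            NONE: NONE,
            LOW_DEPTH: LOW_DEPTH,
        }
        assert poolscan.classify_site(r2, PARAMS) == mapping[
            poolscan.classify_site(r1, PARAMS)
        ]


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "site_class", "depth_m", "depth_f"]
    )


class TestDepthRatio:
    def test_symmetry_gives_zero(self):
        assert poolscan.depth_ratio(37.0, 37.0, 1000.0, 1000.0) == 0.0

    def test_closed_form(self):
        assert poolscan.depth_ratio(9, 4, 100.0, 100.0) == pytest.approx(1.0)

    def test_doubling_in_large_depth_limit(self):
        assert poolscan.depth_ratio(20000, 10000, 1e6, 1e6) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_refuses_nonpositive_library(self):
        with pytest.raises(ValueError):
            poolscan.depth_ratio(1, 1, 0.0, 1.0)


class TestWindowScan:
    def test_clipped_window_counts_both_sites(self):
        sites = sites_frame(
            [("LG1", 1_000, MALE_SPECIFIC, 50, 50),
             ("LG1", 50_000, MALE_SPECIFIC, 50, 50)]
        )
        windows = poolscan.window_scan(sites, PARAMS, {"LG1": 75_000})
        at_25k = windows[windows["pos"] == 25_000].iloc[0]
        assert at_25k["male_snp"] == 2

    def test_no_classified_sites_gives_zero_track(self):
        sites = sites_frame([("LG1", 500, NONE, 50, 50)])
        windows = poolscan.window_scan(sites, PARAMS, {"LG1": 50_000})
        assert (windows["male_snp"] == 0).all()
        assert (windows["female_snp"] == 0).all()

    def test_site_beyond_chromosome_rejected(self):
        sites = sites_frame([("LG1", 60_000, NONE, 50, 50)])
        with pytest.raises(ValueError, match="beyond"):
            poolscan.window_scan(sites, PARAMS, {"LG1": 50_000})

    def test_matches_brute_force_on_random_sites(self):
        rng = np.random.default_rng(7)
        n = 2_000
        length = 300_000
        params = PoolScanParams(window_size=20_000, output_resolution=1_000)
        pos = np.sort(rng.integers(1, length + 1, size=n))
        classes = rng.choice(
            [MALE_SPECIFIC, FEMALE_SPECIFIC, NONE, LOW_DEPTH], size=n
        )
        sites = sites_frame(
            [("LG1", int(p), c, 50, 50) for p, c in zip(pos, classes)]
        )
        fast = poolscan.window_scan(sites, params, {"LG1": length})
        slow = brute_force_windows(sites, params, {"LG1": length})
        np.testing.assert_array_equal(
            fast["male_snp"].to_numpy(), slow["male_snp"].to_numpy()
        )
        np.testing.assert_array_equal(
            fast["female_snp"].to_numpy(), slow["female_snp"].to_numpy()
        )

    def test_chromosome_without_sites_still_emits_windows(self):
        sites = sites_frame([("LG1", 500, MALE_SPECIFIC, 50, 50)])
        windows = poolscan.window_scan(
            sites, PARAMS, {"LG1": 10_000, "LG2": 10_000}
        )
        assert set(windows["chrom"]) == {"LG1", "LG2"}


def synthetic_windows(chrom_counts, res=500):
    """Build a window table from {chrom: array of male counts}."""
    frames = []
    for chrom, counts in chrom_counts.items():
        counts = np.asarray(counts)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.arange(res, res * (len(counts) + 1), res),
                    "male_snp": counts,
                    "female_snp": 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestCallSDR:
    def test_single_planted_region_recovered(self, small_genome):
        truth = make_balanced_truth(n_xy=15, n_xx_males=0, n_females=15)
        params = simdata.PopulationParams(seed=5, pool_depth=50.0)
        records = simdata.simulate_sync(truth, small_genome, params)
        sites = poolscan.classify_sites(records, PARAMS)
        windows = poolscan.window_scan(sites, PARAMS, small_genome.chrom_lengths)
        calls = poolscan.call_sdr(
            windows,
            policy=SDRPolicy(min_span=400_000),
            params=PARAMS,
            chrom_lengths=small_genome.chrom_lengths,
        )
        assert len(calls) == 1
        _, start, end = small_genome.sdr
        assert poolscan.reciprocal_overlap(
            calls[0].start, calls[0].end, start, end
        ) >= 0.8

    def test_no_planted_region_yields_no_call(self):
        """Scans of genomes without a Y-divergent region stay call-free."""
        genome = simdata.GenomeModel(
            linkage_groups=(("LG1", 3_000_000), ("LG2", 3_000_000)),
            sdr=("LG1", 1, 1_000_000),
            background_snp_rate=2e-4,
            y_divergent_rate=0.0,  # no planted region
        )
        false_calls = 0
        for seed in range(20):
            truth = make_balanced_truth(n_xy=15, n_xx_males=0, n_females=15)
            params = simdata.PopulationParams(seed=seed, pool_depth=50.0)
            records = simdata.simulate_sync(truth, genome, params)
            sites = poolscan.classify_sites(records, PARAMS)
            windows = poolscan.window_scan(sites, PARAMS, genome.chrom_lengths)
            calls = poolscan.call_sdr(
                windows, params=PARAMS, chrom_lengths=genome.chrom_lengths
            )
            false_calls += bool(calls)
        assert false_calls <= 1  # >= 95% of seeds clean

    def test_two_regions_beyond_merge_gap_give_two_calls(self):
        counts = np.zeros(20_000, dtype=int)  # 10 Mb at 500 bp resolution
        counts[2000:2900] = 50   # 450 kb hot span
        counts[12000:12900] = 50  # second span, ~4.5 Mb away
        windows = synthetic_windows({"LG1": counts})
        calls = poolscan.call_sdr(
            windows, policy=SDRPolicy(min_span=400_000), params=PARAMS
        )
        assert len(calls) == 2

    def test_regions_within_merge_gap_are_merged(self):
        counts = np.zeros(20_000, dtype=int)
        counts[2000:2900] = 50
        counts[3500:4400] = 50   # flagged spans ~200 kb apart (< 500 kb)
        windows = synthetic_windows({"LG1": counts})
        calls = poolscan.call_sdr(
            windows, policy=SDRPolicy(min_span=400_000), params=PARAMS
        )
        assert len(calls) == 1

    def test_all_zero_genome_returns_empty(self):
        windows = synthetic_windows({"LG1": np.zeros(1000, dtype=int)})
        assert poolscan.call_sdr(windows, params=PARAMS) == []

    def test_empty_window_table_refused(self):
        with pytest.raises(ValueError):
            poolscan.call_sdr(pd.DataFrame(), params=PARAMS)

    def test_deterministic(self):
        counts = np.zeros(5_000, dtype=int)
        counts[1000:3500] = 40
        windows = synthetic_windows({"LG1": counts})
        a = poolscan.call_sdr(windows, policy=SDRPolicy(min_span=400_000),
                              params=PARAMS)
        b = poolscan.call_sdr(windows, policy=SDRPolicy(min_span=400_000),
                              params=PARAMS)
        assert a == b


class TestWriters:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        call = poolscan.SDRCall("LG22", 14_000_001, 26_000_000, 10, 5.0, 9.0)
        path = tmp_path / "sdr.bed"
        poolscan.write_sdr_bed([call], path)
        chrom, start, end, name = path.read_text().split()
        assert (chrom, int(start), int(end)) == ("LG22", 14_000_000, 26_000_000)

    def test_chrom_lengths_roundtrip(self, small_genome, tmp_path):
        path = tmp_path / "lengths.tsv"
        simdata.write_chrom_lengths(small_genome, path)
        assert poolscan.read_chrom_lengths(path) == small_genome.chrom_lengths
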