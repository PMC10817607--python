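"""Binned depth, anomaly flagging and mapping-rate accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from centroscan.core import DepthTrack, FormatError, Genome
from centroscan.coverage import (
    bin_depth,
    flag_anomalies,
    flag_mq0_bins,
    mapping_rates,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "mapq"])


@pytest.fixture(scope="module")
def flat_genome():
    return Genome({"c1": "A" * 40_000})


class TestBinDepth:
    def test_full_bin_read_gives_unit_depth(self, flat_genome):
        track, _ = bin_depth(make_table([("r", "c1", 0, 10_000, 60)]), flat_genome)
        assert track.values["c1"][0] == 1.0
        assert track.values["c1"][1] == 0.0

    def test_straddling_read_splits_proportionally(self, flat_genome):
        track, _ = bin_depth(
            make_table([("r", "c1", 5_000, 15_000, 60)]), flat_genome
        )
        assert track.values["c1"][0] == pytest.approx(0.5)
        assert track.values["c1"][1] == pytest.approx(0.5)

    def test_aligned_bp_exactly_conserved(self, sim):
        track, mean = bin_depth(sim.table, sim.genome, 10_000)
        total_from_bins = 0.0
        for chrom, vec in track.values.items():
            L = len(sim.genome[chrom])
            edges = np.arange(0, L, 10_000)
            widths = np.minimum(edges + 10_000, L) - edges
            total_from_bins += float((vec * widths).sum())
        total_aligned = int((sim.table["end"] - sim.table["start"]).sum())
        assert total_from_bins == pytest.approx(total_aligned, abs=1e-6 * total_aligned)
        assert mean == pytest.approx(total_aligned / sim.genome.total_length())

    def test_unknown_chromosome_is_fatal(self, flat_genome):
        with pytest.raises(FormatError, match="unknown chromosome"):
            bin_depth(make_table([("r", "cX", 0, 10, 60)]), flat_genome)


class TestAnomalies:
    def test_published_rule_on_illustrative_bins(self):
        """Depths [248,248,60,248] under the absolute-80 rule flag bin 3."""
        g = Genome({"c1": "A" * 40_000})
        track = DepthTrack(10_000, {"c1": np.array([248.0, 248.0, 60.0, 248.0])})
        flagged = flag_anomalies(track, g, "absolute", 80.0)
        assert [(iv.start, iv.end) for iv in flagged] == [(20_000, 30_000)]

    def test_clean_track_yields_empty_flags(self):
        g = Genome({"c1": "A" * 30_000})
        track = DepthTrack(10_000, {"c1": np.full(3, 250.0)})
        assert len(flag_anomalies(track, g, "absolute", 80.0)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_flagged_bins_equal_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = Genome({"c1": "A" * 200_000})
        vec = rng.uniform(0, 300, size=20)
        track = DepthTrack(10_000, {"c1": vec})
        flagged = flag_anomalies(track, g, "absolute", 80.0)
        mask = np.zeros(20, dtype=bool)
        for iv in flagged:
            mask[iv.start // 10_000 : -(-iv.end // 10_000)] = True
        assert np.array_equal(mask, vec < 80.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        g = Genome({"c1": "A" * 300_000})
        track = DepthTrack(10_000, {"c1": rng.uniform(0, 300, size=30)})

        def flagged_bins(threshold):
            bins = set()
            for iv in flag_anomalies(track, g, "absolute", threshold):
                bins.update(range(iv.start // 10_000, -(-iv.end // 10_000)))
            return bins

        previous = set()
        for threshold in (20, 50, 80, 150, 290):
            current = flagged_bins(threshold)
            assert previous <= current
            previous = current

    def test_nonpositive_threshold_fatal(self, sim):
        with pytest.raises(FormatError):
            flag_anomalies(sim.depth, sim.genome, "absolute", 0)

    def test_fraction_mode_tracks_genome_mean(self, sim):
        """The simulated coverage dip is recovered in depth-scaled mode."""
        flagged = flag_anomalies(
            sim.depth, sim.genome, "fraction", 0.32, genome_mean=None
        )
        (true_iv, _), = sim.truth.anomalies
        assert any(iv.overlaps(true_iv) for iv in flagged)
        for iv in flagged:
            assert iv.overlaps(true_iv)


class TestMq0:
    def test_all_mq0_bin_flagged_and_empty_bin_not(self):
        g = Genome({"c1": "A" * 30_000})
        rows = [(f"r{i}", "c1", 1000, 9000, 0) for i in range(10)]
        flagged = flag_mq0_bins(make_table(rows), g, 10_000, 0.5)
        assert [(iv.start, iv.end) for iv in flagged] == [(0, 10_000)]

    def test_simulated_collapsed_repeat_region_recovered(self, sim):
        flagged = flag_mq0_bins(sim.table, sim.genome, 10_000, 0.5)
        (true_iv,) = sim.truth.mq0_regions
        covered = [iv for iv in flagged if iv.overlaps(true_iv)]
        assert covered
        # interior bins of the planted region must all be flagged
        lo = true_iv.start // 10_000 + 1
        hi = true_iv.end // 10_000 - 1
        for b in range(lo, hi + 1):
            assert any(
                iv.start <= b * 10_000 and iv.end >= (b + 1) * 10_000
                for iv in covered
            )

    def test_matches_brute_force_fraction_count(self, sim):
        flagged = flag_mq0_bins(sim.table, sim.genome, 10_000, 0.5)
        mask = {
            (iv.chrom, b)
            for iv in flagged
            for b in range(iv.start // 10_000, -(-iv.end // 10_000))
        }
        for chrom in sim.genome.names:
            nb = -(-len(sim.genome[chrom]) // 10_000)
            sub = sim.table[sim.table["chrom"] == chrom]
            for b in range(nb):
                lo, hi = b * 10_000, (b + 1) * 10_000
                over = sub[(sub["start"] < hi) & (sub["end"] > lo)]
                expect = len(over) > 0 and (over["mapq"] == 0).mean() >= 0.5
                assert ((chrom, b) in mask) == expect


class TestMappingRates:
    def test_published_worked_example(self):
        r = mapping_rates(574_965, 29_810, 604_780)
        assert r.pct_nuclear == 95.07

    def test_all_unmapped(self):
        r = mapping_rates(0, 0, 100)
        assert (r.pct_nuclear, r.pct_mito, r.pct_unmapped) == (0.0, 0.0, 100.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        total=st.integers(1, 10**7),
        frac_a=st.floats(0, 1),
        frac_b=st.floats(0, 1),
    )
    def test_percentages_sum_to_hundred(self, total, frac_a, frac_b):
        a = int(total * frac_a)
        b = int((total - a) * frac_b)
        r = mapping_rates(a, b, total)
        assert r.n_nuclear + r.n_mito + r.n_unmapped == total
        assert r.pct_nuclear + r.pct_mito + r.pct_unmapped == pytest.approx(
            100.0, abs=0.02
        )

    def test_zero_total_fatal(self):
        with pytest.raises(FormatError):
            mapping_rates(0, 0, 0)
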