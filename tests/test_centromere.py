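"""Feature tracks, observed/expected transform, centromere calls, arm typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from centroscan.centromere import (
    ArmClassification,
    call_centromeres,
    classify_arms,
    classify_from_arms,
    compute_feature_tracks,
    compute_oe,
)
from centroscan.core import (
    ContactMatrix,
    DepthTrack,
    FormatError,
    Genome,
    IntervalTrack,
    Interval,
)
from centroscan.simulate import (
    SimulationParams,
    simulate_contacts,
    simulate_genome,
)


class TestFeatureTracks:
    def test_all_gc_window_is_one(self):
        g = Genome({"c": "G" * 5000 + "A" * 5000})
        ft = compute_feature_tracks(
            g,
            IntervalTrack("gene"),
            IntervalTrack("repeat"),
            DepthTrack(5000, {"c": np.zeros(2)}),
            window=5000,
        )
        assert ft.gc["c"][0] == 1.0 and ft.gc["c"][1] == 0.0

    def test_fully_covered_window_density_one(self):
        g = Genome({"c": "A" * 10_000})
        genes = IntervalTrack("gene", [Interval("c", 0, 5000)])
        ft = compute_feature_tracks(
            g, genes, IntervalTrack("repeat"),
            DepthTrack(5000, {"c": np.zeros(2)}), window=5000,
        )
        assert ft.gene_density["c"][0] == 1.0
        assert ft.gene_density["c"][1] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_centromere_windows_lower_gc_than_flanks(self, seed):
        params = SimulationParams(seed=seed)
        genome, truth, genes, repeats, rna = simulate_genome(params)
        ft = compute_feature_tracks(genome, genes, repeats, rna, window=10_000)
        for chrom, cen in truth.centromeres.items():
            b0, b1 = cen.start // 10_000, -(-cen.end // 10_000)
            cen_gc = ft.gc[chrom][b0:b1].mean()
            flank = np.r_[ft.gc[chrom][:b0], ft.gc[chrom][b1:]].mean()
            assert cen_gc < flank


@pytest.fixture(scope="module")
def noiseless():
    params = SimulationParams(seed=2, hic_noise=0.0, hic_cen_enrichment=1.0)
    genome, truth, *_ = simulate_genome(params)
    return simulate_contacts(genome, truth, params)


class TestOe:
    def test_decay_only_matrix_gives_unit_oe(self, noiseless):
        oe = compute_oe(noiseless)
        chrom_of = noiseless.bin_chrom()
        cis = chrom_of[:, None] == chrom_of[None, :]
        assert np.allclose(oe.oe[cis], 1.0)
        assert np.allclose(oe.oe[~cis], 1.0)

    def test_per_diagonal_cis_mean_is_exactly_one(self, sim):
        oe = compute_oe(sim.contacts)
        for chrom in sim.genome.names:
            bins = oe.chrom_bins(chrom)
            block = oe.oe[bins.start : bins.stop, bins.start : bins.stop]
            for d in range(block.shape[0]):
                assert abs(np.diagonal(block, d).mean() - 1.0) < 1e-9

    def test_doubled_trans_entry_doubles_its_oe(self):
        sizes = {"a": 100_000, "b": 100_000}
        n = 20
        counts = np.full((n, n), 4.0)
        counts[3, 15] = counts[15, 3] = 8.0
        cm = ContactMatrix(10_000, sizes, counts)
        oe = compute_oe(cm)
        background = oe.oe[2, 14]
        assert oe.oe[3, 15] == pytest.approx(2 * background, rel=0.05)

    def test_all_zero_matrix_is_fatal(self):
        cm = ContactMatrix(10_000, {"a": 50_000}, np.zeros((5, 5)))
        with pytest.raises(FormatError, match="no signal"):
            compute_oe(cm)


class TestCalling:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_centromere_recovered_at_3x_enrichment(self, seed):
        params = SimulationParams(seed=seed, hic_cen_enrichment=3.0)
        genome, truth, genes, repeats, rna = simulate_genome(params)
        cm = simulate_contacts(genome, truth, params)
        oe = compute_oe(cm)
        ft = compute_feature_tracks(genome, genes, repeats, rna, window=10_000)
        calls = call_centromeres(oe, ft, genome)
        for chrom, call in calls.items():
            true = truth.centromeres[chrom]
            assert call.called, (seed, chrom)
            assert abs(call.midpoint - true.midpoint) <= len(true) // 2

    def test_uniform_matrix_and_flat_features_give_no_call(self):
        g = Genome({"a": "A" * 100_000, "b": "A" * 100_000})
        counts = np.full((20, 20), 5.0)
        cm = ContactMatrix(10_000, g.lengths, counts)
        oe = compute_oe(cm)
        ft = compute_feature_tracks(
            g,
            IntervalTrack("gene"),
            IntervalTrack("repeat"),
            DepthTrack(10_000, {"a": np.zeros(10), "b": np.zeros(10)}),
            window=10_000,
        )
        calls = call_centromeres(oe, ft, g)
        assert not any(c.called for c in calls.values())

    def test_edge_centromere_annotated_low_confidence(self):
        params = SimulationParams(
            seed=9, centromere_fraction=(0.04, 0.3, 0.7), hic_cen_enrichment=5.0
        )
        genome, truth, genes, repeats, rna = simulate_genome(params)
        cm = simulate_contacts(genome, truth, params)
        oe = compute_oe(cm)
        ft = compute_feature_tracks(genome, genes, repeats, rna, window=10_000)
        calls = call_centromeres(oe, ft, genome)
        assert calls["chr1"].called
        assert calls["chr1"].low_confidence
        assert not calls["chr2"].low_confidence


TABLE_ROWS = [
    # (s, l, printed_d, printed_r, printed_type) — self-consistent rows
    ("Chr 02", 1.55, 8.45, 6.90, 5.45, "subtelocentric"),
    ("Chr 03", 3.81, 6.19, 2.38, 1.62, "metacentric"),
    ("Chr 06", 4.18, 5.82, 1.64, 1.39, "metacentric"),
    ("Chr 08", 2.49, 7.51, 5.02, 3.02, "subtelocentric"),
    ("Chr 11", 0.33, 9.67, 9.34, 29.30, "acrocentric"),
    ("Chr 12", 0.25, 9.75, 9.50, 39.00, "acrocentric"),
    ("Chr 13", 0.39, 9.61, 9.22, 24.64, "acrocentric"),
]

ALL_TYPES = [
    ("Chr 01", 2.50, 7.50, "submetacentric"),
    ("Chr 02", 1.55, 8.45, "subtelocentric"),
    ("Chr 03", 3.81, 6.19, "metacentric"),
    ("Chr 04", 4.92, 5.08, "metacentric"),
    ("Chr 05", 3.62, 6.38, "submetacentric"),
    ("Chr 06", 4.18, 5.82, "metacentric"),
    ("Chr 07", 3.46, 6.54, "submetacentric"),
    ("Chr 08", 2.49, 7.51, "subtelocentric"),
    ("Chr 09", 3.50, 6.50, "submetacentric"),
    ("Chr 10", 4.29, 5.71, "metacentric"),
    ("Chr 11", 0.33, 9.67, "acrocentric"),
    ("Chr 12", 0.25, 9.75, "acrocentric"),
    ("Chr 13", 0.39, 9.61, "acrocentric"),
]


class TestArms:
    @pytest.mark.parametrize("name,s,l,d,r,label", TABLE_ROWS)
    def test_published_rows_reproduced(self, name, s, l, d, r, label):
        cls = classify_from_arms(s, l)
        assert cls.d == pytest.approx(d, abs=0.005)
        assert cls.r == pytest.approx(r, abs=0.005)
        assert cls.type == label

    @pytest.mark.parametrize("name,s,l,label", ALL_TYPES)
    def test_all_karyotype_labels_reproduced(self, name, s, l, label):
        assert classify_from_arms(s, l).type == label

    def test_median_centromere_is_metacentric(self):
        cls = classify_arms(1_000_000, 500_000)
        assert (cls.s, cls.l, cls.d, cls.r) == (5.0, 5.0, 0.0, 1.0)
        assert cls.type == "metacentric"

    def test_boundary_midpoint_fatal(self):
        with pytest.raises(FormatError):
            classify_arms(1000, 0)
        with pytest.raises(FormatError):
            classify_arms(1000, 1000)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        length=st.integers(10_000, 10_000_000),
        frac=st.floats(0.001, 0.999),
    )
    def test_mirror_invariance(self, length, frac):
        mid = int(length * frac)
        if mid <= 0 or mid >= length:
            return
        a = classify_arms(length, mid)
        b = classify_arms(length, length - mid)
        assert a == b
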