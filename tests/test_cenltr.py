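"""Centromeric LTR monomer detection, element assembly and tabulation."""

import numpy as np
import pytest

from centroscan.cenltr import (
    DEFAULT_PBS_MOTIF,
    centromere_colocation,
    copy_table,
    elements_to_track,
    find_monomers,
    pair_elements,
)
from centroscan.core import FormatError, Genome, Interval, revcomp
from centroscan.simulate import SimulationParams, simulate_genome


@pytest.fixture(scope="module")
def annotated(sim):
    hits = find_monomers(sim.genome, sim.truth.ltr_consensus)
    elements = pair_elements(
        hits, sim.genome, pbs_motif=DEFAULT_PBS_MOTIF
    )
    return hits, elements


class TestMonomers:
    def test_exact_planted_copies_all_complete(self, sim, annotated):
        hits, _ = annotated
        truth = sim.truth
        expected = sum(len(el.ltrs) for els in truth.ltr_elements.values() for el in els)
        assert len(hits) == expected
        assert all(h.klass == "complete" for h in hits)
        assert all(h.identity == 1.0 for h in hits)
        # every planted LTR interval is recovered at exact coordinates
        planted = {
            (iv.chrom, iv.start, iv.end)
            for els in truth.ltr_elements.values()
            for el in els
            for iv in el.ltrs
        }
        found = {(h.chrom, h.interval.start, h.interval.end) for h in hits}
        assert found == planted

    def test_truncated_copy_classified_shorter(self):
        rng = np.random.default_rng(0)
        cons = "".join(rng.choice(list("ACGT"), size=427))
        bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        seq = bg(2000) + cons[: 427 // 2] + bg(2000)
        g = Genome({"c": seq})
        hits = find_monomers(g, cons)
        assert len(hits) == 1 and hits[0].klass == "shorter"

    def test_exhaustive_oracle_on_small_fixture(self):
        """Hit coordinates equal full-scan alignment on a 50 kb fixture."""
        rng = np.random.default_rng(5)
        cons = "".join(rng.choice(list("ACGT"), size=427))
        bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        layout = [bg(9000), cons, bg(11000), revcomp(cons), bg(8000), cons, bg(20000)]
        seq = "".join(layout)
        g = Genome({"c": seq})
        hits = find_monomers(g, cons)
        starts = [9000, 9000 + 427 + 11000, 9000 + 427 + 11000 + 427 + 8000]
        strands = ["+", "-", "+"]
        assert [(h.interval.start, h.strand) for h in hits] == list(
            zip(starts, strands)
        )

    def test_lowering_identity_never_removes_hits(self, sim):
        strict = find_monomers(sim.genome, sim.truth.ltr_consensus, min_identity=0.95)
        loose = find_monomers(sim.genome, sim.truth.ltr_consensus, min_identity=0.80)
        strict_keys = {(h.chrom, h.interval.start) for h in strict}
        loose_keys = {(h.chrom, h.interval.start) for h in loose}
        assert strict_keys <= loose_keys

    def test_n_heavy_consensus_rejected(self, sim):
        with pytest.raises(FormatError, match="N"):
            find_monomers(sim.genome, "N" * 300 + "ACGT" * 25)


class TestElements:
    def test_planted_layout_recovered_exactly(self, sim, annotated):
        _, elements = annotated
        for chrom, planted in sim.truth.ltr_elements.items():
            got = [e for e in elements if e.chrom == chrom]
            assert [e.type for e in got] == [el.kind for el in planted]

    def test_paired_elements_have_all_structural_marks(self, sim, annotated):
        _, elements = annotated
        planted_tsrs = {
            el.tsr
            for els in sim.truth.ltr_elements.values()
            for el in els
            if el.kind == "paired"
        }
        for el in (e for e in elements if e.type == "paired"):
            assert el.tsr in planted_tsrs
            assert el.domain_order_ok
            assert el.pbs_found
            assert el.ppt_found

    def test_every_hit_lands_in_exactly_one_element(self, annotated):
        hits, elements = annotated
        used = sum(2 if e.type == "paired" else 1 for e in elements)
        assert used == len(hits)

    def test_single_isolated_hit_becomes_solo(self):
        rng = np.random.default_rng(3)
        cons = "".join(rng.choice(list("ACGT"), size=427))
        bg = "".join(rng.choice(list("ACGT"), size=3000))
        g = Genome({"c": bg + cons + bg})
        hits = find_monomers(g, cons)
        elements = pair_elements(hits, g)
        assert [e.type for e in elements] == ["solo"]

    def test_scrambled_domain_order_flags_false(self):
        """An element whose internal markers are out of order is flagged."""
        from centroscan.cenltr import DOMAIN_MARKERS

        rng = np.random.default_rng(4)
        cons = "".join(rng.choice(list("ACGT"), size=427))
        bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        internal = list(bg(3000))
        scrambled = ("RH", "RT", "INT", "GAG")
        for i, name in enumerate(scrambled):
            at = 200 + i * 600
            internal[at : at + len(DOMAIN_MARKERS[name])] = DOMAIN_MARKERS[name]
        seq = bg(2000) + cons + "".join(internal) + cons + bg(2000)
        g = Genome({"c": seq})
        elements = pair_elements(find_monomers(g, cons), g)
        assert [e.type for e in elements] == ["paired"]
        assert not elements[0].domain_order_ok

    def test_recovery_tolerates_moderate_mutation(self):
        params = SimulationParams(seed=8, ltr_mutation_rate=0.05)
        genome, truth, *_ = simulate_genome(params)
        hits = find_monomers(genome, truth.ltr_consensus)
        elements = pair_elements(hits, genome)
        for chrom, planted in truth.ltr_elements.items():
            got_paired = sum(e.type == "paired" for e in elements if e.chrom == chrom)
            got_solo = sum(e.type == "solo" for e in elements if e.chrom == chrom)
            want_paired = sum(el.kind == "paired" for el in planted)
            want_solo = sum(el.kind == "solo" for el in planted)
            assert abs(got_paired - want_paired) <= 1
            assert abs(got_solo - want_solo) <= 1

    def test_strand_symmetry_of_counts(self, sim, annotated):
        flipped = Genome(
            {c: revcomp(s) for c, s in sim.genome.sequences.items()}
        )
        hits = find_monomers(flipped, sim.truth.ltr_consensus)
        elements = pair_elements(hits, flipped, pbs_motif=DEFAULT_PBS_MOTIF)
        _, orig_elements = annotated
        for chrom in sim.genome.names:
            for etype in ("paired", "solo"):
                assert sum(
                    e.type == etype and e.chrom == chrom for e in elements
                ) == sum(
                    e.type == etype and e.chrom == chrom for e in orig_elements
                )


class TestReports:
    def test_colocation_all_planted_inside_centromeres(self, sim, annotated):
        _, elements = annotated
        calls = {
            chrom: type("Call", (), {"region": iv})()
            for chrom, iv in sim.truth.centromeres.items()
        }
        report = centromere_colocation(elements, calls)
        assert report.fraction_inside == 1.0

    def test_arm_element_reported_outside(self, sim, annotated):
        _, elements = annotated
        calls = {
            chrom: type("Call", (), {"region": iv})()
            for chrom, iv in sim.truth.centromeres.items()
        }
        outsider = elements[0].__class__(
            type="solo",
            chrom="chr1",
            strand="+",
            five_prime_ltr=None,
            three_prime_ltr=None,
            internal=None,
            solo_ltr=Interval("chr1", 10_000, 10_427),
            tsr=None,
            domain_order_ok=False,
            pbs_found=False,
            ppt_found=False,
        )
        report = centromere_colocation(elements + [outsider], calls)
        inside, outside = report.per_chrom["chr1"]
        assert outside == 1
        assert report.fraction_inside < 1.0

    def test_copy_table_conserves_counts(self, annotated):
        hits, elements = annotated
        table = copy_table(elements, hits)
        assert table["monomers"].sum() == len(hits)
        assert (table["complete"] + table["shorter"]).sum() == len(hits)

    def test_empty_inputs_give_empty_table(self):
        table = copy_table([], [])
        assert len(table) == 0

    def test_elements_track_is_valid(self, sim, annotated):
        _, elements = annotated
        track = elements_to_track(elements)
        track.validate_against(sim.genome)
        assert len(track) == len(elements)
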