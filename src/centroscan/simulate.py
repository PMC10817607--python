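"""Synthetic genome, read, track and Hi-C matrix generator.

Emulates, at desk scale, the structure of a fungal telomere-to-telomere
assembly: GC-rich chromosomes capped by (CCCTAA)n / (TTAGGG)n telomere
arrays, AT-shifted centromeres carrying *Copia*-style LTR retrotransposons
(paired full-length elements and solo monomers), a terminal rDNA tandem
array, long reads with coverage dips over collapsed repeats, and contact
matrices with power-law distance decay plus centromere-centromere
enrichment.  Every planted feature is recorded in a truth object so the
analysis stages can be tested against exact ground truth.

Determinism: one root seed; each component (sequence, reads, contacts, ...)
draws from its own derived generator, so adding a component never perturbs
the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ContactMatrix,
    DepthTrack,
    Genome,
    Interval,
    IntervalTrack,
    n_bins_for,
    revcomp,
)

# Planted elements carry the structural hallmarks the annotation stage
# verifies: the shared domain markers and PBS motif, plus an all-purine
# tract immediately upstream of the 3' LTR.
from .cenltr import DEFAULT_PBS_MOTIF, DOMAIN_MARKERS, DOMAIN_ORDER  # noqa: E402

DEFAULT_PPT = "GGGAGGAGGGAG"

_COMPONENT_IDS = {
    "sequence": 1,
    "features": 2,
    "reads": 3,
    "contacts": 4,
    "unit_seqs": 5,
}


@dataclass(frozen=True)
class LtrPlan:
    """Plan for one planted LTR element."""

    kind: str  # "paired" | "solo"
    internal_length: int = 3000
    tsr_length: int = 5


@dataclass
class SimulationParams:
    """All knobs of the synthetic generator (seed is mandatory)."""

    seed: int
    n_chroms: int = 3
    chrom_lengths: tuple[int, ...] = (500_000, 400_000, 300_000)
    gc_background: float = 0.56
    telomere_unit: str = "CCCTAA"
    telomere_copies: int = 30
    centromere_fraction: tuple[float, ...] = (0.45, 0.30, 0.70)
    centromere_width: int = 30_000
    centromere_gc: float = 0.40
    ltr_monomer_length: int = 427
    ltr_layout: tuple[tuple[LtrPlan, ...], ...] | None = None
    ltr_mutation_rate: float = 0.0
    rdna_unit_length: int = 5701
    rdna_copies: int = 10
    rdna_chrom_end: tuple[str, str] | None = ("chr3", "3p")
    missing_telomeres: tuple[tuple[str, str], ...] = ()
    read_length_mean: int = 8000
    read_length_sd: int = 1500
    read_depth: float = 30.0
    read_error_rate: float = 0.001
    depth_bin_size: int = 10_000
    anomaly_regions: tuple[tuple[str, int, int, float], ...] = (
        ("chr2", 150_000, 170_000, 0.3),
    )
    mq0_regions: tuple[tuple[str, int, int], ...] = (("chr1", 60_000, 80_000),)
    hic_bin_size: int = 10_000
    hic_decay_exponent: float = 1.0
    hic_cis_scale: float = 100.0
    hic_trans_scale: float = 1.0
    hic_cen_enrichment: float = 5.0
    hic_noise: float = 0.1
    rna_bin_size: int = 10_000
    rna_depth_background: float = 20.0
    rna_depth_centromere: float = 0.5
    gene_length: int = 1500
    gene_spacing: int = 1500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths must list one length per chromosome")
        if len(self.centromere_fraction) != self.n_chroms:
            raise ValueError("centromere_fraction must match n_chroms")
        for frac, length in zip(self.centromere_fraction, self.chrom_lengths):
            mid = int(frac * length)
            if not (0 < mid - self.centromere_width // 2
                    and mid + self.centromere_width // 2 < length):
                raise ValueError("centromere span outside chromosome")
        for value in (self.read_depth, self.gc_background, self.centromere_gc):
            if value <= 0:
                raise ValueError("depths, lengths and fractions must be positive")
        for _, start, end, factor in self.anomaly_regions:
            if not (0 < factor <= 1) or start >= end:
                raise ValueError("anomaly regions need 0 < depth_factor <= 1")
        if self.ltr_layout is None:
            default = (
                (LtrPlan("paired"), LtrPlan("paired"), LtrPlan("solo")),
                (LtrPlan("paired"), LtrPlan("solo"), LtrPlan("solo")),
                (LtrPlan("paired"), LtrPlan("solo")),
            )
            self.ltr_layout = tuple(
                default[i % len(default)] for i in range(self.n_chroms)
            )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, _COMPONENT_IDS[component]))
        )


@dataclass
class PlantedLtr:
    """Truth record of one planted LTR element."""

    kind: str
    strand: str
    ltrs: list[Interval]
    internal: Interval | None
    tsr: str
    domain_order: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature (the test oracle)."""

    telomere_ends: list[tuple[str, str]] = field(default_factory=list)
    centromeres: dict[str, Interval] = field(default_factory=dict)
    ltr_elements: dict[str, list[PlantedLtr]] = field(default_factory=dict)
    ltr_consensus: str = ""
    rdna: Interval | None = None
    rdna_copies: int = 0
    rdna_unit: str = ""
    anomalies: list[tuple[Interval, float]] = field(default_factory=list)
    mq0_regions: list[Interval] = field(default_factory=list)
    read_origins: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def encode(obj):
            if isinstance(obj, Interval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end,
                        "strand": obj.strand, "label": obj.label}
            raise TypeError(type(obj))

        payload = {
            "telomere_ends": self.telomere_ends,
            "centromeres": {c: encode(iv) for c, iv in self.centromeres.items()},
            "ltr_elements": {
                c: [
                    {
                        "kind": el.kind,
                        "strand": el.strand,
                        "ltrs": [encode(iv) for iv in el.ltrs],
                        "internal": encode(el.internal) if el.internal else None,
                        "tsr": el.tsr,
                        "domain_order": list(el.domain_order),
                    }
                    for el in els
                ]
                for c, els in self.ltr_elements.items()
            },
            "ltr_consensus": self.ltr_consensus,
            "rdna": encode(self.rdna) if self.rdna else None,
            "rdna_copies": self.rdna_copies,
            "rdna_unit": self.rdna_unit,
            "anomalies": [[encode(iv), f] for iv, f in self.anomalies],
            "mq0_regions": [encode(iv) for iv in self.mq0_regions],
            "read_origins": self.read_origins,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    k = rng.binomial(len(arr), rate)
    if k:
        pos = rng.choice(len(arr), size=k, replace=False)
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
    return _to_str(arr)


def _build_paired_element(
    rng: np.random.Generator, ltr: str, plan: LtrPlan, mutation_rate: float
) -> tuple[str, str, dict[str, tuple[int, int]]]:
    """Return (element_seq_without_tsr, tsr, layout offsets within element)."""
    tsr = _to_str(_random_bases(rng, plan.tsr_length, 0.5))
    internal_len = plan.internal_length
    filler = _to_str(_random_bases(rng, internal_len, 0.5))
    # carve PBS just inside the 5' LTR and PPT just inside the 3' LTR
    internal = list(filler)
    pbs_off = 3
    internal[pbs_off : pbs_off + len(DEFAULT_PBS_MOTIF)] = DEFAULT_PBS_MOTIF
    ppt_off = internal_len - len(DEFAULT_PPT)
    internal[ppt_off:] = DEFAULT_PPT
    usable = range(
        pbs_off + len(DEFAULT_PBS_MOTIF) + 10, ppt_off - 10
    )
    marker_span = len(usable)
    for i, name in enumerate(DOMAIN_ORDER):
        marker = DOMAIN_MARKERS[name]
        at = usable.start + (i * marker_span) // len(DOMAIN_ORDER)
        internal[at : at + len(marker)] = marker
    internal_seq = "".join(internal)
    five = _mutate(rng, ltr, mutation_rate)
    three = _mutate(rng, ltr, mutation_rate)
    element = five + internal_seq + three
    layout = {
        "five_ltr": (0, len(five)),
        "internal": (len(five), len(five) + internal_len),
        "three_ltr": (len(five) + internal_len, len(element)),
    }
    return element, tsr, layout


def simulate_genome(
    params: SimulationParams,
) -> tuple[Genome, SyntheticTruth, IntervalTrack, IntervalTrack, DepthTrack]:
    """Generate the genome plus truth, gene/repeat tracks and RNA depth."""
    rng = params.rng("sequence")
    rng_units = params.rng("unit_seqs")
    truth = SyntheticTruth()
    truth.ltr_consensus = _to_str(
        _random_bases(rng_units, params.ltr_monomer_length, 0.5)
    )
    truth.rdna_unit = _to_str(_random_bases(rng_units, params.rdna_unit_length, 0.5))
    truth.rdna_copies = params.rdna_copies

    unit = params.telomere_unit
    telo_len = len(unit) * params.telomere_copies
    sequences: dict[str, str] = {}
    gene_ivs: list[Interval] = []
    repeat_ivs: list[Interval] = []
    rna_values: dict[str, np.ndarray] = {}

    for ci, chrom in enumerate(params.chrom_names()):
        L = params.chrom_lengths[ci]
        arr = _random_bases(rng, L, params.gc_background)

        # centromere: AT-shifted window carrying the LTR array
        mid = int(params.centromere_fraction[ci] * L)
        cen_start = mid - params.centromere_width // 2
        cen_end = cen_start + params.centromere_width
        arr[cen_start:cen_end] = _random_bases(
            rng, cen_end - cen_start, params.centromere_gc
        )
        cen_iv = Interval(chrom, cen_start, cen_end, label="centromere")
        truth.centromeres[chrom] = cen_iv

        # plant LTR elements; paired elements on '+', solos on '-', solo
        # spacing kept below the pairing gap so solos never chain together
        elements: list[PlantedLtr] = []
        cursor = cen_start + 500
        for plan in params.ltr_layout[ci]:
            if plan.kind == "paired":
                element, tsr, layout = _build_paired_element(
                    rng, truth.ltr_consensus, plan, params.ltr_mutation_rate
                )
                full = tsr + element + tsr
                arr[cursor : cursor + len(full)] = np.frombuffer(
                    full.encode(), dtype=np.uint8
                )
                el_start = cursor + len(tsr)
                ivs = {
                    key: Interval(chrom, el_start + s, el_start + e, "+", key)
                    for key, (s, e) in layout.items()
                }
                elements.append(
                    PlantedLtr(
                        kind="paired",
                        strand="+",
                        ltrs=[ivs["five_ltr"], ivs["three_ltr"]],
                        internal=ivs["internal"],
                        tsr=tsr,
                        domain_order=DOMAIN_ORDER,
                    )
                )
                repeat_ivs.append(
                    Interval(chrom, cursor, cursor + len(full), "+", "ltr_element")
                )
                cursor += len(full) + 2000
            else:
                mono = _mutate(
                    rng, revcomp(truth.ltr_consensus), params.ltr_mutation_rate
                )
                arr[cursor : cursor + len(mono)] = np.frombuffer(
                    mono.encode(), dtype=np.uint8
                )
                iv = Interval(chrom, cursor, cursor + len(mono), "-", "solo_ltr")
                elements.append(
                    PlantedLtr(
                        kind="solo",
                        strand="-",
                        ltrs=[iv],
                        internal=None,
                        tsr="",
                        domain_order=(),
                    )
                )
                repeat_ivs.append(iv)
                cursor += len(mono) + 450
        if cursor > cen_end:
            raise ValueError(f"planted LTR layout overflows centromere on {chrom}")
        truth.ltr_elements[chrom] = elements

        # pad centromere repeat coverage with satellite-like blocks so the
        # window reads as repeat-dense without further LTR copies
        sat_start = cursor + 300
        while sat_start + 2000 < cen_end:
            repeat_ivs.append(
                Interval(chrom, sat_start, sat_start + 1500, ".", "satellite")
            )
            sat_start += 2000

        # terminal rDNA tandem array (inside the telomere cap, like the
        # rDNA-terminal chromosome of the emulated assembly)
        rdna_span = None
        if params.rdna_chrom_end and params.rdna_chrom_end[0] == chrom:
            end_side = params.rdna_chrom_end[1]
            array = truth.rdna_unit * params.rdna_copies
            missing = (chrom, end_side) in params.missing_telomeres
            pad = 0 if missing else telo_len
            if end_side == "3p":
                start = L - pad - len(array)
                arr[start : start + len(array)] = np.frombuffer(
                    array.encode(), dtype=np.uint8
                )
                rdna_span = Interval(chrom, start, start + len(array), "+", "rdna")
            else:
                arr[pad : pad + len(array)] = np.frombuffer(
                    array.encode(), dtype=np.uint8
                )
                rdna_span = Interval(chrom, pad, pad + len(array), "+", "rdna")
            truth.rdna = rdna_span
            repeat_ivs.append(rdna_span)

        # telomere caps
        if (chrom, "5p") not in params.missing_telomeres:
            cap = unit * params.telomere_copies
            arr[:telo_len] = np.frombuffer(cap.encode(), dtype=np.uint8)
            truth.telomere_ends.append((chrom, "5p"))
            repeat_ivs.append(Interval(chrom, 0, telo_len, "+", "telomere"))
        if (chrom, "3p") not in params.missing_telomeres:
            cap = revcomp(unit) * params.telomere_copies
            arr[L - telo_len :] = np.frombuffer(cap.encode(), dtype=np.uint8)
            truth.telomere_ends.append((chrom, "3p"))
            repeat_ivs.append(Interval(chrom, L - telo_len, L, "+", "telomere"))

        sequences[chrom] = _to_str(arr)

        # gene models tile the arms; none inside the centromere or termini
        pos = telo_len + 200
        arm_end = L - telo_len - 200
        while pos + params.gene_length < arm_end:
            g_end = pos + params.gene_length
            if not (g_end > cen_start and pos < cen_end) and not (
                rdna_span is not None
                and g_end > rdna_span.start
                and pos < rdna_span.end
            ):
                gene_ivs.append(
                    Interval(chrom, pos, g_end, "+" if (pos // 1000) % 2 else "-",
                             f"gene_{chrom}_{pos}")
                )
            pos = g_end + params.gene_spacing

        # RNA depth: background transcription on the arms, near-silence
        # over the centromere (per-bin overlap-weighted)
        nb = n_bins_for(L, params.rna_bin_size)
        vec = np.full(nb, params.rna_depth_background, dtype=float)
        for b in range(nb):
            b0, b1 = b * params.rna_bin_size, min((b + 1) * params.rna_bin_size, L)
            overlap = max(0, min(b1, cen_end) - max(b0, cen_start))
            f = overlap / (b1 - b0)
            vec[b] = (1 - f) * params.rna_depth_background + (
                f * params.rna_depth_centromere
            )
        rna_values[chrom] = vec

    genome = Genome(sequences)
    for chrom, start, end, factor in params.anomaly_regions:
        truth.anomalies.append((Interval(chrom, start, end, label="anomaly"), factor))
    for chrom, start, end in params.mq0_regions:
        truth.mq0_regions.append(Interval(chrom, start, end, label="mq0"))
    gene_track = IntervalTrack("gene", gene_ivs)
    repeat_track = IntervalTrack("repeat", repeat_ivs)
    rna_depth = DepthTrack(params.rna_bin_size, rna_values)
    return genome, truth, gene_track, repeat_track, rna_depth


def simulate_reads(
    genome: Genome, truth: SyntheticTruth, params: SimulationParams
) -> tuple[dict[str, str], pd.DataFrame, DepthTrack]:
    """Sample long reads; returns (reads, alignment table, binned depth).

    Reads are uniform over each chromosome except inside anomaly regions,
    where sampling is thinned by the configured depth factor.  Per-base
    errors are i.i.d. substitutions.  The alignment table records true
    origins; the depth track is the exact binned coverage of those origins.
    """
    rng = params.rng("reads")
    reads: dict[str, str] = {}
    rows: list[tuple[str, str, int, int, int]] = []
    anomalies = [(iv, f) for iv, f in truth.anomalies]
    mq0 = truth.mq0_regions

    for chrom in genome.names:
        seq = genome[chrom]
        L = len(seq)
        n_target = int(round(params.read_depth * L / params.read_length_mean))
        count = 0
        for i in range(n_target):
            li = max(500, int(round(rng.normal(params.read_length_mean,
                                               params.read_length_sd))))
            s0 = int(rng.integers(1 - li, L))
            start, end = max(0, s0), min(L, s0 + li)
            if end - start < 200:
                continue
            midpoint = (start + end) // 2
            factor = 1.0
            for iv, f in anomalies:
                if iv.chrom == chrom and iv.contains_point(midpoint):
                    factor = f
                    break
            if factor < 1.0 and rng.random() >= factor:
                continue
            rid = f"r_{chrom}_{count:06d}"
            count += 1
            read = _mutate(rng, seq[start:end], params.read_error_rate)
            mapq = 60
            for iv in mq0:
                if iv.chrom == chrom and start < iv.end and iv.start < end:
                    mapq = 0
                    break
            reads[rid] = read
            rows.append((rid, chrom, start, end, mapq))
            truth.read_origins[rid] = (chrom, start, end)
        if count == 0:
            import warnings

            warnings.warn(f"no reads sampled for {chrom}")

    table = pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "mapq"])

    # exact binned coverage of the true origins
    bs = params.depth_bin_size
    values = {}
    for chrom in genome.names:
        L = len(genome[chrom])
        diff = np.zeros(L + 1)
        sub = table[table["chrom"] == chrom]
        np.add.at(diff, sub["start"].to_numpy(), 1)
        np.add.at(diff, sub["end"].to_numpy(), -1)
        per_base = np.cumsum(diff[:-1])
        edges = np.arange(0, L, bs)
        sums = np.add.reduceat(per_base, edges)
        widths = np.minimum(edges + bs, L) - edges
        values[chrom] = sums / widths
    depth = DepthTrack(bs, values)
    return reads, table, depth


def simulate_contacts(
    genome: Genome, truth: SyntheticTruth, params: SimulationParams
) -> ContactMatrix:
    """Generate a symmetric binned contact matrix.

    Cis expectation is ``cis_scale / (d + 1) ** decay_exponent`` at bin
    distance ``d``; trans background is constant; pairs of centromeric bins
    are multiplied by the enrichment factor; multiplicative log-normal
    noise (unit mean) with the configured dispersion is applied.
    """
    rng = params.rng("contacts")
    bs = params.hic_bin_size
    sizes = genome.lengths
    n = sum(n_bins_for(s, bs) for s in sizes.values())
    expected = np.full((n, n), params.hic_trans_scale, dtype=float)
    offsets, cursor = {}, 0
    for chrom, size in sizes.items():
        nb = n_bins_for(size, bs)
        offsets[chrom] = cursor
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :])
        block = params.hic_cis_scale / (d + 1.0) ** params.hic_decay_exponent
        expected[cursor : cursor + nb, cursor : cursor + nb] = block
        cursor += nb

    cen_bins = np.zeros(n, dtype=bool)
    for chrom, iv in truth.centromeres.items():
        b0 = offsets[chrom] + iv.start // bs
        b1 = offsets[chrom] + (iv.end - 1) // bs
        cen_bins[b0 : b1 + 1] = True
    enrich = np.outer(cen_bins, cen_bins)
    expected = np.where(enrich, expected * params.hic_cen_enrichment, expected)

    if params.hic_noise > 0:
        sigma = params.hic_noise
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=(n, n))
        noise = np.triu(noise) + np.triu(noise, 1).T
        counts = expected * noise
    else:
        counts = expected
    counts = (counts + counts.T) / 2
    return ContactMatrix(bs, dict(sizes), counts)


def write_outputs(
    out_dir: str | Path, params: SimulationParams
) -> None:
    """Run the full simulation and write every artifact to ``out_dir``."""
    from . import core

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth, genes, repeats, rna = simulate_genome(params)
    reads, table, depth = simulate_reads(genome, truth, params)
    contacts = simulate_contacts(genome, truth, params)
    core.write_fasta(genome, out / "genome.fasta")
    core.write_fastq(reads, out / "reads.fastq")
    core.write_gff3(genes, out / "genes.gff3")
    core.write_gff3(repeats, out / "repeats.gff3")
    core.write_bedgraph(rna, out / "rna_depth.bedgraph", genome.lengths)
    core.write_bedgraph(depth, out / "read_depth.bedgraph", genome.lengths)
    core.write_alignment_table(table, out / "alignments.tsv")
    core.write_contacts(contacts, out / "contacts.txt")
    truth.to_json(out / "truth.json")
    with open(out / "units.fasta", "w") as fh:
        fh.write(f">ltr_consensus\n{truth.ltr_consensus}\n")
        fh.write(f">rdna_unit\n{truth.rdna_unit}\n")
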