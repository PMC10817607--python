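"""Structural annotation of centromeric Copia-style LTR retrotransposons.

The monomer scan locates copies of an LTR consensus (both strands,
identity- and coverage-scored); pairing assembles same-strand monomer
pairs separated by a plausible internal region into full-length elements
and leaves the remainder as solo LTRs.  Paired elements are checked for
the structural hallmarks of an intact element: identical target-site
repeats (TSR) flanking the element, a primer binding site (PBS) just
inside the 5' LTR, a polypurine tract (PPT) just inside the 3' LTR, and
the internal protein domains in Copia order GAG -> INT -> RT -> RH
(matched as nucleotide marker sequences).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from . import _seqmatch
from .core import FormatError, Genome, Interval, IntervalTrack, log, revcomp

PBS_SEARCH_WINDOW = 20
PPT_SEARCH_WINDOW = 30
PPT_MIN_RUN = 10

# Nucleotide marker sequences for the internal protein-coding domains of a
# Copia element, in their canonical order.  Detection is a marker-sequence
# match, not a protein-profile search; callers may supply their own markers.
DOMAIN_MARKERS: dict[str, str] = {
    "GAG": "ATGGCAGGTAAACCTCGTGGACTTCAAGAA",
    "INT": "ATGGATCGTACAGGTCATGAACTGGCTTCA",
    "RT": "ATGCCATTGACTGAAGTTCGTGCAGATAAC",
    "RH": "ATGTCAGAACATCTGGTTCGAGCTGGTACT",
}
DOMAIN_ORDER = ("GAG", "INT", "RT", "RH")

# tRNA-iMet-style primer binding site used by the synthetic generator; the
# PBS check reports not-found unless a motif is supplied.
DEFAULT_PBS_MOTIF = "TGGTATCAGAGC"


@dataclass(frozen=True)
class LtrMonomerHit:
    chrom: str
    interval: Interval
    strand: str
    identity: float
    coverage_of_consensus: float
    klass: str  # "complete" | "shorter"
    q_start: int = 0  # matched span on the strand-oriented consensus
    q_end: int = 0


@dataclass
class LtrElement:
    type: str  # "paired" | "solo"
    chrom: str
    strand: str
    five_prime_ltr: Interval | None
    three_prime_ltr: Interval | None
    internal: Interval | None
    solo_ltr: Interval | None
    tsr: str | None
    domain_order_ok: bool
    pbs_found: bool
    ppt_found: bool

    @property
    def span(self) -> Interval:
        ivs = [
            iv
            for iv in (self.five_prime_ltr, self.three_prime_ltr, self.solo_ltr)
            if iv is not None
        ]
        return Interval(
            self.chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            self.strand,
            self.type,
        )


def find_monomers(
    genome: Genome,
    consensus_seq: str,
    min_identity: float = 0.80,
    complete_cov: float = 0.80,
    short_cov: float = 0.40,
    seed_k: int = 21,
    seed_step: int = 2,
) -> list[LtrMonomerHit]:
    """Scan the genome for LTR monomer copies and classify them.

    Hits covering at least ``complete_cov`` of the consensus are complete;
    hits in [``short_cov``, ``complete_cov``) are shorter homologs; hits
    below ``short_cov`` are dropped.  Overlapping hits are reduced to the
    best-scoring one.
    """
    if not (50 <= len(consensus_seq) <= 2000):
        raise FormatError("LTR consensus must be 50-2000 bp")
    if consensus_seq.count("N") / len(consensus_seq) > 0.2:
        raise FormatError("LTR consensus contains more than 20% N")
    min_len = max(20, int(short_cov * len(consensus_seq)))
    hits: list[LtrMonomerHit] = []
    for chrom, seq in genome.sequences.items():
        raw = _seqmatch.seed_extend_hits(
            seq,
            consensus_seq,
            seed_k=seed_k,
            min_identity=min_identity,
            min_len=min_len,
            step=seed_step,
        )
        for h in _seqmatch.reduce_overlapping_hits(raw):
            klass = "complete" if h.q_cov >= complete_cov else "shorter"
            hits.append(
                LtrMonomerHit(
                    chrom=chrom,
                    interval=Interval(chrom, h.start, h.end, h.strand, "ltr"),
                    strand=h.strand,
                    identity=h.identity,
                    coverage_of_consensus=h.q_cov,
                    klass=klass,
                    q_start=h.q_start,
                    q_end=h.q_end,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.interval.start))
    log.info(
        "LTR monomers: %d complete, %d shorter",
        sum(h.klass == "complete" for h in hits),
        sum(h.klass == "shorter" for h in hits),
    )
    return hits


def _find_tsr(seq: str, left_end: int, right_start: int, tsr_min: int, tsr_max: int) -> str | None:
    """Longest identical flanking duplication of length tsr_min..tsr_max."""
    for t in range(tsr_max, tsr_min - 1, -1):
        if left_end - t < 0 or right_start + t > len(seq):
            continue
        left = seq[left_end - t : left_end]
        right = seq[right_start : right_start + t]
        if left == right and "N" not in left:
            return left
    return None


def _has_ppt(region: str) -> bool:
    return re.search(r"[AG]{%d,}" % PPT_MIN_RUN, region) is not None


def pair_elements(
    hits: list[LtrMonomerHit],
    genome: Genome,
    internal_min: int = 1000,
    internal_max: int = 15_000,
    ltr_pair_identity: float = 0.85,
    tsr_min: int = 4,
    tsr_max: int = 6,
    pbs_motif: str | None = None,
    domain_markers: dict[str, str] | None = None,
    domain_order: tuple[str, ...] = DOMAIN_ORDER,
) -> list[LtrElement]:
    """Assemble monomer hits into paired elements and solo LTRs.

    Greedy left-to-right: each unpaired hit pairs with the next same-
    strand hit whose separation lies in [internal_min, internal_max] and
    whose sequence aligns at >= ``ltr_pair_identity``; unpaired hits
    become solo elements.  Every hit lands in exactly one element.
    """
    markers = domain_markers if domain_markers is not None else DOMAIN_MARKERS
    elements: list[LtrElement] = []
    by_chrom: dict[str, list[LtrMonomerHit]] = {}
    for h in sorted(hits, key=lambda h: (h.chrom, h.interval.start)):
        by_chrom.setdefault(h.chrom, []).append(h)

    for chrom, chrom_hits in by_chrom.items():
        seq = genome[chrom]
        used = [False] * len(chrom_hits)
        for i, h1 in enumerate(chrom_hits):
            if used[i]:
                continue
            partner = None
            for j in range(i + 1, len(chrom_hits)):
                if used[j]:
                    continue
                h2 = chrom_hits[j]
                if h2.strand != h1.strand:
                    continue
                sep = h2.interval.start - h1.interval.end
                if sep < internal_min:
                    continue
                if sep > internal_max:
                    break
                # compare base-aligned through shared consensus coordinates
                ov_s = max(h1.q_start, h2.q_start)
                ov_e = min(h1.q_end, h2.q_end)
                if ov_e - ov_s < 50:
                    continue
                s1 = seq[
                    h1.interval.start + ov_s - h1.q_start :
                    h1.interval.start + ov_e - h1.q_start
                ]
                s2 = seq[
                    h2.interval.start + ov_s - h2.q_start :
                    h2.interval.start + ov_e - h2.q_start
                ]
                if _seqmatch.identity_ungapped(s1, s2) >= ltr_pair_identity:
                    partner = j
                    break
            if partner is None:
                elements.append(
                    LtrElement(
                        type="solo",
                        chrom=chrom,
                        strand=h1.strand,
                        five_prime_ltr=None,
                        three_prime_ltr=None,
                        internal=None,
                        solo_ltr=h1.interval,
                        tsr=None,
                        domain_order_ok=False,
                        pbs_found=False,
                        ppt_found=False,
                    )
                )
                used[i] = True
                continue
            h2 = chrom_hits[partner]
            used[i] = used[partner] = True
            left, right = h1.interval, h2.interval
            strand = h1.strand
            internal_iv = Interval(chrom, left.end, right.start, strand, "internal")
            tsr = _find_tsr(seq, left.start, right.end, tsr_min, tsr_max)

            # orient element-internal checks by strand
            internal_seq = seq[left.end : right.start]
            if strand == "+":
                five_iv, three_iv = left, right
                oriented_internal = internal_seq
            else:
                five_iv, three_iv = right, left
                oriented_internal = revcomp(internal_seq)
            pbs_window = PBS_SEARCH_WINDOW + (len(pbs_motif) if pbs_motif else 0)
            pbs_found = bool(pbs_motif) and pbs_motif in oriented_internal[:pbs_window]
            ppt_found = _has_ppt(oriented_internal[-PPT_SEARCH_WINDOW:])

            positions = []
            ok = True
            for name in domain_order:
                at = oriented_internal.find(markers[name])
                if at == -1:
                    ok = False
                    break
                positions.append(at)
            domain_order_ok = ok and positions == sorted(positions)

            elements.append(
                LtrElement(
                    type="paired",
                    chrom=chrom,
                    strand=strand,
                    five_prime_ltr=five_iv,
                    three_prime_ltr=three_iv,
                    internal=internal_iv,
                    solo_ltr=None,
                    tsr=tsr,
                    domain_order_ok=domain_order_ok,
                    pbs_found=pbs_found,
                    ppt_found=ppt_found,
                )
            )
    log.info(
        "LTR elements: %d paired, %d solo",
        sum(e.type == "paired" for e in elements),
        sum(e.type == "solo" for e in elements),
    )
    return elements


@dataclass
class ColocationReport:
    per_chrom: dict[str, tuple[int, int]]  # (inside, outside)
    fraction_inside: float


def centromere_colocation(
    elements: list[LtrElement], calls: dict[str, "object"]
) -> ColocationReport:
    """Count elements inside vs outside the called centromere regions."""
    per_chrom: dict[str, tuple[int, int]] = {}
    inside_total = outside_total = 0
    for el in elements:
        call = calls.get(el.chrom)
        region = getattr(call, "region", None) if call is not None else None
        inside = region is not None and el.span.overlaps(region)
        i, o = per_chrom.get(el.chrom, (0, 0))
        per_chrom[el.chrom] = (i + inside, o + (not inside))
        inside_total += inside
        outside_total += not inside
    total = inside_total + outside_total
    return ColocationReport(
        per_chrom, inside_total / total if total else float("nan")
    )


def copy_table(
    elements: list[LtrElement], hits: list[LtrMonomerHit]
):
    """Per-chromosome counts of complete/shorter monomers and paired/solo."""
    chroms = sorted({h.chrom for h in hits} | {e.chrom for e in elements})
    rows = []
    for chrom in chroms:
        ch_hits = [h for h in hits if h.chrom == chrom]
        ch_els = [e for e in elements if e.chrom == chrom]
        rows.append(
            {
                "chrom": chrom,
                "complete": sum(h.klass == "complete" for h in ch_hits),
                "shorter": sum(h.klass == "shorter" for h in ch_hits),
                "monomers": len(ch_hits),
                "paired": sum(e.type == "paired" for e in ch_els),
                "solo": sum(e.type == "solo" for e in ch_els),
            }
        )
    return pd.DataFrame(rows)


def elements_to_track(elements: list[LtrElement]) -> IntervalTrack:
    intervals = []
    for el in elements:
        span = el.span
        label = (
            f"type={el.type};tsr={el.tsr or '.'};domains={int(el.domain_order_ok)};"
            f"pbs={int(el.pbs_found)};ppt={int(el.ppt_found)}"
        )
        intervals.append(
            Interval(span.chrom, span.start, span.end, el.strand, label)
        )
    return IntervalTrack("ltr_hit", intervals)
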