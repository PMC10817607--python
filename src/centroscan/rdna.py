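"""rDNA unit matching and copy-number estimation.

Copy number follows the blast-coverage identity: the total matched length
of the repeat unit across sequencing reads, divided by (genome-wide
average coverage x unit length), rounded to the nearest integer.  Hits are
found by ungapped seed-and-extend on both strands; overlapping hits on the
same sequence are merged before lengths are summed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

from . import _seqmatch
from .core import FormatError, Genome, Interval, IntervalTrack, log, merge_intervals


@dataclass
class RdnaEstimate:
    unit_length: int
    total_matched_length: int
    genome_coverage: float
    copy_number: int
    raw_ratio: float
    hits: IntervalTrack | None = None


def find_unit_hits(
    sequences: Mapping[str, str],
    unit_seq: str,
    seed_k: int = 31,
    min_identity: float = 0.9,
    min_hit_len: int = 100,
    seed_step: int = 4,
) -> tuple[IntervalTrack, int]:
    """Locate unit matches in a set of sequences; returns (track, L_total).

    Overlapping hits on the same sequence are merged before the total
    matched length is summed, so tandem unit arrays contribute their full
    footprint exactly once.
    """
    if not unit_seq:
        raise FormatError("empty rDNA unit sequence")
    if seed_k > len(unit_seq):
        raise FormatError("seed_k longer than the unit sequence")
    longest_homopolymer = max(
        len(run) for run in re.findall(r"(?:A+|C+|G+|T+|N+)", unit_seq)
    )
    if longest_homopolymer >= seed_k:
        warnings.warn(
            "degenerate (homopolymer-like) unit sequence; merged hit lengths "
            "may be inflated"
        )
    intervals: list[Interval] = []
    total = 0
    for name, seq in sequences.items():
        hits = _seqmatch.seed_extend_hits(
            seq,
            unit_seq,
            seed_k=seed_k,
            min_identity=min_identity,
            min_len=min_hit_len,
            step=seed_step,
        )
        merged = merge_intervals(
            Interval(name, h.start, h.end, h.strand, "rdna") for h in hits
        )
        intervals.extend(merged)
        total += sum(len(iv) for iv in merged)
    track = IntervalTrack("rdna_hit", intervals)
    log.info("rDNA hits: %d merged intervals, %d bp total", len(track), total)
    return track, total


def rdna_copy_number(
    L_total: int, C: float, U: int, hits: IntervalTrack | None = None
) -> RdnaEstimate:
    """Copy number = round(L_total / (C x U)) to the nearest integer."""
    if C <= 0 or U <= 0:
        raise FormatError("coverage and unit length must be positive")
    if L_total < 0:
        raise FormatError("total matched length must be non-negative")
    ratio = L_total / (C * U)
    copy_number = int(ratio + 0.5)
    log.info("rDNA copy number: %.2f -> %d", ratio, copy_number)
    return RdnaEstimate(
        unit_length=U,
        total_matched_length=L_total,
        genome_coverage=C,
        copy_number=copy_number,
        raw_ratio=ratio,
        hits=hits,
    )


@dataclass
class TerminalEndReport:
    chrom: str
    end: str
    covered_fraction: float
    rdna_terminal: bool


def terminal_rdna_check(
    genome: Genome,
    unit_seq: str,
    window: int = 20_000,
    flag_fraction: float = 0.5,
    seed_k: int = 31,
    min_identity: float = 0.9,
    min_hit_len: int = 100,
) -> list[TerminalEndReport]:
    """Fraction of each terminal window covered by unit hits.

    Ends with more than ``flag_fraction`` of the window covered are
    flagged as rDNA-terminal (the signature of an rDNA-blocked telomere).
    """
    reports = []
    for chrom, seq in genome.sequences.items():
        win = min(window, len(seq))
        for end, sub in (("5p", seq[:win]), ("3p", seq[-win:])):
            hits = _seqmatch.seed_extend_hits(
                sub,
                unit_seq,
                seed_k=seed_k,
                min_identity=min_identity,
                min_len=min(min_hit_len, win),
            )
            merged = merge_intervals(
                Interval(chrom, h.start, h.end, h.strand, "rdna") for h in hits
            )
            covered = sum(len(iv) for iv in merged) / win
            reports.append(
                TerminalEndReport(chrom, end, covered, covered > flag_fraction)
            )
    return reports


def estimate_from_reads(
    reads: Mapping[str, str],
    unit_seq: str,
    coverage: float,
    seed_k: int = 31,
    min_identity: float = 0.9,
    min_hit_len: int = 100,
    seed_step: int = 4,
) -> RdnaEstimate:
    """End-to-end estimate: match the unit in reads, apply the formula."""
    hits, total = find_unit_hits(
        reads,
        unit_seq,
        seed_k=seed_k,
        min_identity=min_identity,
        min_hit_len=min_hit_len,
        seed_step=seed_step,
    )
    return rdna_copy_number(total, coverage, len(unit_seq), hits)
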