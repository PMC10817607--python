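"""Binned depth, coverage-anomaly flagging, MQ0 dominance and mapping rates.

Depth is computed over tiled non-overlapping bins (default 10 kb); a bin's
depth is the aligned base pairs falling in it divided by its true width,
so total aligned bp is exactly conserved by binning.  Anomalies are bins
below an absolute depth cutoff (the published rule: depth < 80 at a
genome-wide average of 248) or, for depth-scaled runs, below a fraction of
the genome-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .core import (
    DepthTrack,
    FormatError,
    Genome,
    Interval,
    IntervalTrack,
    log,
    n_bins_for,
)


def bin_depth(
    table: pd.DataFrame, genome: Genome, bin_size: int = 10_000
) -> tuple[DepthTrack, float]:
    """Bin an alignment table into mean depths; returns (track, genome mean).

    Each alignment contributes its overlap bp to every bin it straddles;
    the final partial bin is normalized by its true width.  The genome
    mean is the length-weighted mean of bin depths (= aligned bp / genome
    length).
    """
    values: dict[str, np.ndarray] = {}
    unknown = set(table["chrom"]) - set(genome.names)
    if unknown:
        row = table[table["chrom"].isin(unknown)].iloc[0]
        raise FormatError(f"alignment on unknown chromosome: {row.to_dict()}")
    total_bp = 0
    for chrom in genome.names:
        L = len(genome[chrom])
        sub = table[table["chrom"] == chrom]
        if ((sub["start"] < 0) | (sub["end"] > L)).any():
            bad = sub[(sub["start"] < 0) | (sub["end"] > L)].iloc[0]
            raise FormatError(f"alignment outside {chrom}: {bad.to_dict()}")
        diff = np.zeros(L + 1)
        np.add.at(diff, sub["start"].to_numpy(), 1.0)
        np.add.at(diff, sub["end"].to_numpy(), -1.0)
        per_base = np.cumsum(diff[:-1])
        edges = np.arange(0, L, bin_size)
        sums = np.add.reduceat(per_base, edges) if L else np.zeros(0)
        widths = np.minimum(edges + bin_size, L) - edges
        values[chrom] = sums / widths
        total_bp += int((sub["end"] - sub["start"]).sum())
    genome_mean = total_bp / genome.total_length()
    log.info("binned depth: genome mean %.2f at %d bp bins", genome_mean, bin_size)
    return DepthTrack(bin_size, values), genome_mean


@dataclass
class CoverageReport:
    bin_size: int
    genome_mean: float
    depth: DepthTrack
    anomalies: IntervalTrack
    mq0_flagged: IntervalTrack


def _merge_flagged_bins(
    flagged: dict[str, np.ndarray], bin_size: int, lengths: dict[str, int], kind: str
) -> IntervalTrack:
    intervals = []
    for chrom, mask in flagged.items():
        idx = np.flatnonzero(
            np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
        )
        for b0, b1 in zip(idx[::2], idx[1::2]):
            start = int(b0) * bin_size
            end = min(int(b1) * bin_size, lengths[chrom])
            intervals.append(Interval(chrom, start, end, ".", kind))
    return IntervalTrack(kind, intervals)


def flag_anomalies(
    depth: DepthTrack,
    genome: Genome,
    mode: str = "absolute",
    threshold: float = 80.0,
    genome_mean: float | None = None,
) -> IntervalTrack:
    """Flag low-coverage bins; adjacent flagged bins merge into one interval.

    ``absolute`` mode flags bins with depth < threshold; ``fraction`` mode
    flags bins with depth < threshold x genome_mean.  Flagging is monotone
    in the threshold.
    """
    if threshold <= 0:
        raise FormatError("threshold must be positive")
    if mode not in {"absolute", "fraction"}:
        raise FormatError(f"unknown anomaly mode {mode!r}")
    if mode == "fraction":
        if genome_mean is None:
            widths = {
                c: np.minimum(
                    np.arange(len(v)) * depth.bin_size + depth.bin_size,
                    len(genome[c]),
                )
                - np.arange(len(v)) * depth.bin_size
                for c, v in depth.values.items()
            }
            num = sum((depth.values[c] * widths[c]).sum() for c in depth.values)
            den = sum(widths[c].sum() for c in depth.values)
            genome_mean = float(num / den)
        cutoff = threshold * genome_mean
    else:
        cutoff = threshold
    flagged = {chrom: vec < cutoff for chrom, vec in depth.values.items()}
    track = _merge_flagged_bins(flagged, depth.bin_size, genome.lengths, "anomaly")
    log.info("coverage anomalies: %d intervals below %.3g", len(track), cutoff)
    return track


def flag_mq0_bins(
    table: pd.DataFrame,
    genome: Genome,
    bin_size: int = 10_000,
    min_mq0_fraction: float = 0.5,
) -> IntervalTrack:
    """Flag bins dominated by mapping-quality-0 reads.

    A bin is flagged iff it is overlapped by at least one read and the
    fraction of overlapping reads with mapq 0 is >= ``min_mq0_fraction``.
    """
    flagged: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        nb = n_bins_for(len(genome[chrom]), bin_size)
        totals = np.zeros(nb)
        mq0 = np.zeros(nb)
        sub = table[table["chrom"] == chrom]
        for start, end, mapq in zip(sub["start"], sub["end"], sub["mapq"]):
            b0, b1 = start // bin_size, (end - 1) // bin_size
            totals[b0 : b1 + 1] += 1
            if mapq == 0:
                mq0[b0 : b1 + 1] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mq0 / np.maximum(totals, 1), 0.0)
        flagged[chrom] = (totals > 0) & (frac >= min_mq0_fraction)
    return _merge_flagged_bins(flagged, bin_size, genome.lengths, "anomaly")


@dataclass
class MappingRateReport:
    n_total: int
    n_nuclear: int
    n_mito: int
    n_unmapped: int
    pct_nuclear: float
    pct_mito: float
    pct_unmapped: float


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def mapping_rates(n_nuclear: int, n_mito: int, n_total: int) -> MappingRateReport:
    """Mapping-rate accounting: percentages to 2 decimals (round half-up)."""
    if n_total == 0:
        raise FormatError("n_total must be positive")
    if n_nuclear + n_mito > n_total:
        raise FormatError("nuclear + mito reads exceed total")
    n_unmapped = n_total - n_nuclear - n_mito
    return MappingRateReport(
        n_total=n_total,
        n_nuclear=n_nuclear,
        n_mito=n_mito,
        n_unmapped=n_unmapped,
        pct_nuclear=_pct(n_nuclear, n_total),
        pct_mito=_pct(n_mito, n_total),
        pct_unmapped=_pct(n_unmapped, n_total),
    )


def coverage_report(
    table: pd.DataFrame,
    genome: Genome,
    bin_size: int = 10_000,
    mode: str = "absolute",
    threshold: float = 80.0,
    min_mq0_fraction: float = 0.5,
) -> CoverageReport:
    """Full coverage stage: depth, anomaly flags and MQ0 dominance flags."""
    depth, genome_mean = bin_depth(table, genome, bin_size)
    anomalies = flag_anomalies(depth, genome, mode, threshold, genome_mean)
    mq0 = flag_mq0_bins(table, genome, bin_size, min_mq0_fraction)
    return CoverageReport(bin_size, genome_mean, depth, anomalies, mq0)
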