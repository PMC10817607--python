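"""Canonical k-mer accounting, consensus-accuracy (QV) arithmetic and the
peak-based genome-size estimate.

The consensus error model treats every distinct assembly k-mer that is
absent from the read k-mer set as evidence of error; with ``K_only`` such
k-mers out of ``K_total``, the per-base error estimate is

    E = 1 - (1 - K_only / K_total) ** (1 / k)

and QV = -10 log10(E), accuracy% = (1 - E) x 100.  Both ``K_total`` and
``K_only`` count DISTINCT canonical k-mers: for this assembly-scale
arithmetic the distinct count (tens of millions) rather than the
positional count is the only reading consistent with the published use
of the formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import FormatError, log

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_DECODE = "ACGT"


@dataclass
class KmerSet:
    """Distinct canonical k-mers (2-bit packed uint64 codes) with counts."""

    k: int
    codes: np.ndarray  # sorted unique uint64
    counts: np.ndarray  # multiplicity of each code

    @property
    def n_distinct(self) -> int:
        return len(self.codes)

    @property
    def n_instances(self) -> int:
        return int(self.counts.sum())

    def decode(self, code: int) -> str:
        return "".join(
            _DECODE[(int(code) >> (2 * (self.k - 1 - j))) & 3] for j in range(self.k)
        )


def _sequence_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of every N-free window of ``seq``."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    bad = arr == 255
    if bad.any():
        # a window is invalid if it contains any N
        cum = np.concatenate(([0], np.cumsum(bad)))
        valid = (cum[k:] - cum[:-k]) == 0
    base = arr.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    comp = (3 - base) & np.uint64(3)
    for j in range(k):
        fwd |= (base[j : j + n] & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        # reverse complement: position j maps to rc position k-1-j
        rev |= (comp[j : j + n] & np.uint64(3)) << np.uint64(2 * j)
    canonical = np.minimum(fwd, rev)
    return canonical[valid]


def count_canonical_kmers(sequences: Iterable[str], k: int) -> KmerSet:
    """Count distinct canonical k-mers over a collection of sequences.

    Each k-length window contributes the lexicographic minimum of itself
    and its reverse complement; windows containing N are skipped.
    """
    if k % 2 == 0 or not (3 <= k <= 31):
        raise FormatError("k must be odd and within [3, 31]")
    chunks = [_sequence_codes(seq, k) for seq in sequences]
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        warnings.warn("k longer than every sequence: empty k-mer set")
        return KmerSet(k, np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64))
    allcodes = np.concatenate(chunks)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerSet(k, codes, counts.astype(np.int64))


@dataclass
class KmerQcResult:
    """Consensus-accuracy figures from assembly-vs-read k-mer comparison."""

    k: int
    K_total: int
    K_only: int
    E: float
    QV: float
    accuracy_pct: float

    def to_report(self) -> str:
        qv = "inf" if math.isinf(self.QV) else f"{self.QV:.4f}"
        return (
            f"k\t{self.k}\n"
            f"assembly_kmers\t{self.K_total}\n"
            f"assembly_only_kmers\t{self.K_only}\n"
            f"error_rate\t{self.E:.6g}\n"
            f"QV\t{qv}\n"
            f"accuracy_pct\t{self.accuracy_pct:.4f}\n"
        )


def qv_from_counts(K_only: int, K_total: int, k: int) -> KmerQcResult:
    """Evaluate the k-mer error model from explicit distinct-k-mer counts."""
    if K_total <= 0:
        raise FormatError("K_total must be positive")
    if not 0 <= K_only <= K_total:
        raise FormatError("K_only must lie in [0, K_total]")
    if K_only == 0:
        return KmerQcResult(k, K_total, 0, 0.0, math.inf, 100.0)
    if K_only == K_total:
        warnings.warn("every assembly k-mer is unsupported; E = 1")
        return KmerQcResult(k, K_total, K_only, 1.0, 0.0, 0.0)
    E = 1.0 - (1.0 - K_only / K_total) ** (1.0 / k)
    QV = -10.0 * math.log10(E)
    accuracy_pct = (1.0 - E) * 100.0
    return KmerQcResult(k, K_total, K_only, E, QV, accuracy_pct)


def kmer_qv(assembly_kmers: KmerSet, read_kmers: KmerSet) -> KmerQcResult:
    """Compare distinct assembly k-mers against the read k-mer database.

    A read k-mer present at any multiplicity rescues an assembly k-mer
    (presence/absence only; no minimum-multiplicity filter).
    """
    if assembly_kmers.k != read_kmers.k:
        raise FormatError("assembly and read k-mer sets use different k")
    if assembly_kmers.n_distinct == 0:
        raise FormatError("empty assembly k-mer set")
    present = np.isin(
        assembly_kmers.codes, read_kmers.codes, assume_unique=True
    )
    K_total = assembly_kmers.n_distinct
    K_only = int((~present).sum())
    result = qv_from_counts(K_only, K_total, assembly_kmers.k)
    log.info(
        "kmer qv: %d/%d assembly-only k-mers, accuracy %.4f%%",
        K_only,
        K_total,
        result.accuracy_pct,
    )
    return result


@dataclass
class KmerHistogram:
    """Depth histogram of read k-mers and the peak-based size estimate."""

    k: int
    multiplicities: np.ndarray  # histogram index = multiplicity
    peak_depth: int | None
    genome_size_estimate: float | None


def kmer_histogram(read_kmers: KmerSet) -> KmerHistogram:
    """Histogram read k-mer multiplicities and estimate genome size.

    The homozygous peak is the modal multiplicity above 1; the size
    estimate is total k-mer instances divided by the peak depth.  With no
    peak above multiplicity 1 (e.g. unit-coverage input) the estimate is
    undefined.
    """
    counts = read_kmers.counts
    if len(counts) == 0:
        warnings.warn("empty read k-mer set; no histogram")
        return KmerHistogram(read_kmers.k, np.zeros(1, dtype=np.int64), None, None)
    hist = np.bincount(counts)
    peak = None
    # the homozygous hump must carry more distinct k-mers than the
    # singleton class, otherwise there is no coverage peak above 1
    if len(hist) > 2 and hist[2:].sum() > hist[1]:
        # smooth before peak-picking: depth histograms from modest genomes
        # are lumpy because coverage is correlated over read-length scales
        kernel = np.ones(5) / 5
        smooth = np.convolve(hist.astype(float), kernel, mode="same")
        peak = int(np.argmax(smooth[2:]) + 2)
        if hist[peak] == 0:
            peak = None
    if peak is None:
        warnings.warn("no k-mer multiplicity peak above 1; size estimate undefined")
        return KmerHistogram(read_kmers.k, hist, None, None)
    # refine the modal depth by the centroid of the peak's own mass
    # (proportional window: the homozygous hump, not the error spike)
    lo = max(2, int(0.6 * peak))
    hi = min(len(hist), int(1.5 * peak) + 1)
    m = np.arange(lo, hi)
    refined = float((m * hist[lo:hi]).sum() / hist[lo:hi].sum())
    total_instances = read_kmers.n_instances
    return KmerHistogram(read_kmers.k, hist, peak, total_instances / refined)
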