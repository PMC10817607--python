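"""Shared data model, file formats, configuration and logging.

Every downstream stage consumes the containers defined here; files are
parsed exactly once at the pipeline boundary.  The internal coordinate
convention is 0-based half-open everywhere; GFF3 (1-based closed) is
converted on the way in and back on the way out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("centroscan")

VALID_ALPHABET = frozenset("ACGTN")
VALID_STRANDS = frozenset("+-.")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def configure_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)


class FormatError(ValueError):
    """Raised on malformed input files or invariant violations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Named chromosome sequences (uppercase DNA over A,C,G,T,N)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise FormatError("empty chromosome name")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                offset = min(seq.index(b) for b in bad)
                raise FormatError(
                    f"illegal character {seq[offset]!r} in record "
                    f"{name!r} at offset {offset}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


TRACK_KINDS = frozenset(
    {"gene", "repeat", "anomaly", "ltr_hit", "rdna_hit", "telomere"}
)


@dataclass
class IntervalTrack:
    """Sorted, typed collection of intervals."""

    kind: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise FormatError(f"unknown track kind {self.kind!r}")
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def validate_against(self, genome: Genome) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise FormatError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > len(genome[iv.chrom]):
                raise FormatError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {len(genome[iv.chrom])}"
                )


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals per chromosome (idempotent)."""
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class DepthTrack:
    """Mean depth per fixed-size bin, one vector per chromosome."""

    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise FormatError("bin_size must be positive")
        for name, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if np.any(vec < 0):
                raise FormatError(f"negative depth in {name}")
            self.values[name] = vec

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


def n_bins_for(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def chrom_bin_ranges(bin_size: int, chrom_sizes: dict[str, int]) -> dict[str, range]:
    """Global bin-index range of each chromosome under a fixed bin size."""
    ranges, cursor = {}, 0
    for name, size in chrom_sizes.items():
        nb = n_bins_for(size, bin_size)
        ranges[name] = range(cursor, cursor + nb)
        cursor += nb
    return ranges


@dataclass
class ContactMatrix:
    """Binned symmetric Hi-C contact counts with genome-global bin indexing.

    ``chrom_sizes`` preserves chromosome order; per-chromosome blocks are
    addressed through ``chrom_offsets`` so cis and trans sub-matrices are
    handled uniformly.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.n_bins_total
        if self.counts.shape != (n, n):
            raise FormatError(
                f"counts shape {self.counts.shape} != ({n}, {n})"
            )
        if np.any(self.counts < 0):
            raise FormatError("negative contact counts")
        if not np.allclose(self.counts, self.counts.T):
            raise FormatError("contact matrix is not symmetric")

    @property
    def n_bins_total(self) -> int:
        return sum(
            n_bins_for(size, self.bin_size) for size in self.chrom_sizes.values()
        )

    @property
    def chrom_offsets(self) -> dict[str, int]:
        offsets, cursor = {}, 0
        for name, size in self.chrom_sizes.items():
            offsets[name] = cursor
            cursor += n_bins_for(size, self.bin_size)
        return offsets

    def chrom_bins(self, chrom: str) -> range:
        off = self.chrom_offsets[chrom]
        return range(off, off + n_bins_for(self.chrom_sizes[chrom], self.bin_size))

    def bin_chrom(self) -> np.ndarray:
        """Chromosome index of every global bin."""
        out = np.empty(self.n_bins_total, dtype=int)
        for ci, chrom in enumerate(self.chrom_sizes):
            bins = self.chrom_bins(chrom)
            out[bins.start : bins.stop] = ci
        return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_SPEC: dict[str, tuple[object, float, float]] = {
    # name: (default, min, max) -- validated at load time
    "telomere_unit": ("CCCTAA", None, None),
    "telomere_window": (1000, 1, 1e9),
    "telomere_min_copies": (5, 1, 1e6),
    "telomere_max_mismatch_frac": (1 / 6, 0.0, 1.0),
    "telomere_min_copies_read": (10, 1, 1e6),
    "patch_anchor_len": (500, 20, 1e6),
    "patch_min_anchor_identity": (0.95, 0.0, 1.0),
    "kmer_k": (17, 3, 31),
    "coverage_bin_size": (10_000, 1, 1e9),
    "coverage_mode": ("absolute", None, None),
    "coverage_threshold": (80.0, 1e-12, 1e9),
    "coverage_fraction_threshold": (0.32, 1e-12, 1.0),
    "mq0_min_fraction": (0.5, 0.0, 1.0),
    "rdna_seed_k": (31, 8, 64),
    "rdna_min_identity": (0.9, 0.0, 1.0),
    "rdna_min_hit_len": (100, 1, 1e9),
    "rdna_terminal_window": (20_000, 1, 1e9),
    "oe_d_min": (50, 1, 1e9),
    "oe_epsilon": (1e-9, 0.0, 1.0),
    "centromere_peak_fraction": (0.5, 0.0, 1.0),
    "centromere_smooth_bins": (3, 1, 99),
    "centromere_min_evidence": (2, 0, 4),
    "feature_window": (10_000, 1, 1e9),
    "ltr_min_identity": (0.80, 0.0, 1.0),
    "ltr_complete_cov": (0.80, 0.0, 1.0),
    "ltr_short_cov": (0.40, 0.0, 1.0),
    "ltr_internal_min": (1000, 1, 1e9),
    "ltr_internal_max": (15_000, 1, 1e9),
    "ltr_pair_identity": (0.85, 0.0, 1.0),
    "ltr_tsr_min": (4, 1, 100),
    "ltr_tsr_max": (6, 1, 100),
    "seed": (0, 0, 2**31 - 1),
}


@dataclass
class PipelineConfig:
    """All stage parameters with validated defaults.

    Values come from defaults, overridden by a key-value (YAML) file,
    overridden by explicit keyword arguments (e.g. CLI flags).
    """

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        resolved = {k: spec[0] for k, spec in _CONFIG_SPEC.items()}
        for key, value in self.params.items():
            if key not in _CONFIG_SPEC:
                raise FormatError(f"unknown configuration key {key!r}")
            default, lo, hi = _CONFIG_SPEC[key]
            if lo is not None and not (lo <= float(value) <= hi):
                raise FormatError(
                    f"configuration {key}={value!r} outside [{lo}, {hi}]"
                )
            resolved[key] = type(default)(value) if default is not None else value
        self.params = resolved

    def __getattr__(self, name: str):
        params = object.__getattribute__(self, "params")
        if name in params:
            return params[name]
        raise AttributeError(name)

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        params: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise FormatError(f"config file {path} is not a key-value mapping")
            params.update(loaded)
        params.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(params)
        log.info("resolved configuration: %s", cfg.params)
        return cfg


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Genome:
    """Parse a FASTA file into a :class:`Genome` (record order preserved)."""
    sequences: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"empty or invalid FASTA file: {path}")
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"duplicate record name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> dict[str, str]:
    """Read IDs and uppercase sequences from a FASTQ file."""
    reads: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in reads:
            raise FormatError(f"duplicate read id {rec.id!r} in {path}")
        reads[rec.id] = str(rec.seq).upper()
    return reads


def write_fastq(reads: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads.items():
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED / GFF3 intervals
# ---------------------------------------------------------------------------


def read_intervals(
    path: str | Path,
    dialect: str = "bed",
    kind: str = "gene",
    genome: Genome | None = None,
) -> IntervalTrack:
    """Read BED (0-based half-open) or GFF3 (1-based closed) intervals.

    Output is sorted by (chrom, start); GFF3 coordinates are converted to
    the internal 0-based half-open convention.
    """
    if dialect not in {"bed", "gff3"}:
        raise FormatError(f"unknown dialect {dialect!r}")
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 else "."
                    label = fields[8] if len(fields) > 8 else fields[2]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}")
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end after conversion "
                    f"({start} >= {end})"
                )
            intervals.append(Interval(chrom, start, end, strand, label))
    track = IntervalTrack(kind, intervals)
    if genome is not None:
        track.validate_against(genome)
    return track


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n"
            )


def write_gff3(
    track: IntervalTrack, path: str | Path, source: str = "centroscan"
) -> None:
    """Write GFF3; internal half-open coordinates regain 1-based closed form."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in track:
            attrs = iv.label if "=" in iv.label else f"Name={iv.label or '.'}"
            fh.write(
                f"{iv.chrom}\t{source}\t{track.kind}\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph depth tracks
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path, bin_size: int) -> DepthTrack:
    """Read a bedGraph of fixed-size bins into a :class:`DepthTrack`."""
    per_chrom: dict[str, dict[int, float]] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end, value = int(start), int(end), float(value)
            if start % bin_size != 0:
                raise FormatError(
                    f"{path}:{lineno}: bin start {start} not aligned to "
                    f"bin size {bin_size}"
                )
            per_chrom.setdefault(chrom, {})[start // bin_size] = value
            maxend[chrom] = max(maxend.get(chrom, 0), end)
    values = {}
    for chrom, bins in per_chrom.items():
        vec = np.zeros(n_bins_for(maxend[chrom], bin_size))
        for idx, val in bins.items():
            vec[idx] = val
        values[chrom] = vec
    return DepthTrack(bin_size, values)


def write_bedgraph(
    track: DepthTrack, path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            length = None if chrom_lengths is None else chrom_lengths[chrom]
            for i, val in enumerate(vec):
                start = i * track.bin_size
                end = start + track.bin_size
                if length is not None:
                    end = min(end, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# Contact matrices (triplet or dense text)
# ---------------------------------------------------------------------------


def read_contacts(path: str | Path) -> ContactMatrix:
    """Read a binned contact matrix.

    Header lines declare bin size, chromosome table and encoding::

        #bin_size  10000
        #chrom     chr1  500000
        #format    triplet | dense

    Triplet bodies hold ``bin_i  bin_j  value`` (global bin indices); values
    are assigned symmetrically.  Dense bodies hold whitespace-separated rows.
    """
    bin_size = None
    chrom_sizes: dict[str, int] = {}
    fmt = "triplet"
    body: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if fields[0] == "bin_size":
                    bin_size = int(fields[1])
                elif fields[0] == "chrom":
                    chrom_sizes[fields[1]] = int(fields[2])
                elif fields[0] == "format":
                    fmt = fields[1]
                continue
            body.append(line)
    if bin_size is None or not chrom_sizes:
        raise FormatError(f"{path}: missing #bin_size or #chrom header")
    n = sum(n_bins_for(s, bin_size) for s in chrom_sizes.values())
    counts = np.zeros((n, n))
    if fmt == "triplet":
        for line in body:
            fields = line.split()
            i, j, value = int(fields[0]), int(fields[1]), float(fields[2])
            if not (0 <= i < n and 0 <= j < n):
                raise FormatError(f"{path}: bin index ({i},{j}) out of range")
            if value < 0:
                raise FormatError(f"{path}: negative count at ({i},{j})")
            counts[i, j] = value
            counts[j, i] = value
    elif fmt == "dense":
        rows = [np.array(line.split(), dtype=float) for line in body]
        counts = np.array(rows)
        if counts.shape != (n, n):
            raise FormatError(
                f"{path}: dense matrix shape {counts.shape}, expected ({n},{n})"
            )
        counts = (counts + counts.T) / 2 if not np.allclose(counts, counts.T) else counts
        if np.any(counts < 0):
            raise FormatError(f"{path}: negative counts in dense matrix")
    else:
        raise FormatError(f"{path}: unknown matrix format {fmt!r}")
    return ContactMatrix(bin_size, chrom_sizes, counts)


def write_contacts(
    cm: ContactMatrix, path: str | Path, fmt: str = "triplet"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size\t{cm.bin_size}\n")
        for chrom, size in cm.chrom_sizes.items():
            fh.write(f"#chrom\t{chrom}\t{size}\n")
        fh.write(f"#format\t{fmt}\n")
        if fmt == "triplet":
            n = cm.n_bins_total
            for i in range(n):
                for j in range(i, n):
                    if cm.counts[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{cm.counts[i, j]:.10g}\n")
        else:
            for row in cm.counts:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Alignment tables
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = ["read_id", "chrom", "start", "end", "mapq"]


def read_alignment_table(path: str | Path):
    """Read a tab-separated alignment table (read_id, chrom, start, end, mapq)."""
    import pandas as pd

    table = pd.read_csv(
        path, sep="\t", names=ALIGNMENT_COLUMNS, comment="#", header=0
    )
    if (table["start"] >= table["end"]).any():
        raise FormatError(f"{path}: alignment with start >= end")
    return table


def write_alignment_table(table, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=ALIGNMENT_COLUMNS)
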