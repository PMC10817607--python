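"""Telomere detection and the telomere-rescue (patching) procedure.

A chromosome end carries a telomere when a tandem array of the repeat unit
(CCCTAA at the 5' terminus, its reverse complement TTAGGG at the 3'
terminus) starts within a short terminal scan window.  Ends that lack an
array can be patched from a library of telomere-bearing long reads: the
terminal anchor of the chromosome is matched against each read and the
read extending farthest into a telomere array is spliced on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import _seqmatch
from .core import FormatError, Genome, Interval, log, revcomp

ENDS = ("5p", "3p")


@dataclass(frozen=True)
class EndReport:
    chrom: str
    end: str  # "5p" | "3p"
    present: bool
    copy_count: int
    span: Interval | None


@dataclass
class TelomereReport:
    """Per-chromosome, per-end telomere detection results."""

    ends: dict[tuple[str, str], EndReport] = field(default_factory=dict)

    @property
    def total_telomeres(self) -> int:
        return sum(1 for rep in self.ends.values() if rep.present)

    def present(self, chrom: str, end: str) -> bool:
        return self.ends[(chrom, end)].present

    def to_table(self) -> str:
        lines = ["chrom\tend\tpresent\tcopy_count\tspan"]
        for (chrom, end), rep in sorted(self.ends.items()):
            span = f"{rep.span.start}-{rep.span.end}" if rep.span else "."
            lines.append(
                f"{chrom}\t{end}\t{int(rep.present)}\t{rep.copy_count}\t{span}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class TelomereReadLibrary:
    """Reads oriented so the telomere motif matches the 5'-side unit form."""

    unit: str
    reads: dict[str, str] = field(default_factory=dict)
    copy_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def _check_unit(unit: str) -> int:
    if len(unit) < 4:
        raise FormatError("telomere unit must be at least 4 bp")
    if set(unit) - set("ACGT"):
        raise FormatError(f"telomere unit {unit!r} contains non-ACGT characters")
    return len(unit)


def detect_telomeres(
    genome: Genome,
    unit: str = "CCCTAA",
    window: int = 1000,
    min_copies: int = 5,
    max_mismatch_frac: float = 1 / 6,
) -> TelomereReport:
    """Scan both ends of every chromosome for tandem telomere arrays.

    An end is present iff a tandem run of at least ``min_copies`` units
    (each unit within the per-unit mismatch budget) starts within
    ``window`` bp of the terminus.  The 3' end is scanned for the reverse
    complement of the unit, which makes detection strand-consistent:
    reverse-complementing a chromosome swaps its 5'/3' reports exactly.
    """
    u = _check_unit(unit)
    max_mm = math.floor(max_mismatch_frac * u)
    report = TelomereReport()
    for chrom, seq in genome.sequences.items():
        win = min(window, len(seq))
        scan_len = min(len(seq), win + 100 * u * max(min_copies, 10))
        for end in ENDS:
            # scan in the frame where the unit reads in 5'->3' array order
            frame = seq[:scan_len] if end == "5p" else revcomp(seq[-scan_len:])
            copies, start = _seqmatch.best_tandem_run(frame, unit, max_mm, win)
            copies, start = int(copies), int(start)
            present = copies >= min_copies
            span = None
            if present:
                if end == "5p":
                    span = Interval(chrom, start, start + copies * u, ".", "telomere")
                else:
                    hi = len(seq) - start
                    span = Interval(chrom, hi - copies * u, hi, ".", "telomere")
            report.ends[(chrom, end)] = EndReport(chrom, end, present, copies, span)
    log.info(
        "telomere scan: %d/%d ends present",
        report.total_telomeres,
        2 * len(genome.names),
    )
    return report


def extract_telomeric_reads(
    reads: dict[str, str],
    unit: str = "CCCTAA",
    min_copies_read: int = 10,
) -> TelomereReadLibrary:
    """Extract reads carrying a tandem telomere array, orientation-normalized.

    A read qualifies iff it contains at least ``min_copies_read`` tandem
    copies of the unit or of its reverse complement; reverse-form matches
    are reverse-complemented before inclusion so the whole library shares
    one orientation.  The library is deduplicated by read id.
    """
    _check_unit(unit)
    if min_copies_read < 1:
        raise FormatError("min_copies_read must be >= 1")
    rc_unit = revcomp(unit)
    lib = TelomereReadLibrary(unit=unit)
    for rid, seq in reads.items():
        if rid in lib.reads:
            continue
        fwd = _seqmatch.max_tandem_copies(seq, unit)
        rev = _seqmatch.max_tandem_copies(seq, rc_unit)
        if max(fwd, rev) < min_copies_read:
            continue
        if fwd >= rev:
            lib.reads[rid] = seq
            lib.copy_counts[rid] = fwd
        else:
            lib.reads[rid] = revcomp(seq)
            lib.copy_counts[rid] = rev
    log.info("telomeric read library: %d reads", len(lib))
    return lib


@dataclass(frozen=True)
class PatchReport:
    chrom: str
    end: str
    patched: bool
    read_id: str | None
    extension_length: int
    anchor_identity: float


class PatchError(ValueError):
    """Raised when the requested end already carries a telomere."""


def patch_missing_telomere(
    genome: Genome,
    chrom: str,
    end: str,
    library: TelomereReadLibrary,
    anchor_len: int = 500,
    min_anchor_identity: float = 0.95,
    unit: str = "CCCTAA",
    min_copies: int = 5,
    seed_len: int = 21,
) -> tuple[Genome, PatchReport]:
    """Patch a telomere-missing chromosome end from the read library.

    The terminal ``anchor_len`` bp are matched against each library read
    (exact seed, then full-anchor identity >= ``min_anchor_identity``);
    among anchored reads whose distal portion ends in a telomere array,
    the longest extension wins (ties: higher identity, then smallest read
    id).  With an empty library or no anchored read the genome is
    returned unchanged.
    """
    if end not in ENDS:
        raise FormatError(f"end must be one of {ENDS}")
    pre = detect_telomeres(genome, unit=unit, min_copies=min_copies)
    if pre.present(chrom, end):
        raise PatchError(f"{chrom}:{end} already carries a telomere")

    seq = genome[chrom]
    # canonical frame: the end to patch becomes the 3' terminus
    work = seq if end == "3p" else revcomp(seq)
    anchor = work[-anchor_len:]
    rc_unit = revcomp(unit)
    u = len(unit)

    best: tuple[int, float, str, str] | None = None  # (ext_len, identity, rid, ext)
    for rid in sorted(library.reads):
        # library reads carry the unit form; the 3'-frame needs the rc form
        read = revcomp(library.reads[rid])
        seed = anchor[:seed_len]
        pos = read.find(seed)
        while pos != -1:
            cand = read[pos : pos + anchor_len]
            if len(cand) == anchor_len:
                ident = _seqmatch.identity_ungapped(anchor, cand)
                if ident >= min_anchor_identity:
                    ext = read[pos + anchor_len :]
                    runs = _seqmatch.tandem_runs(ext, rc_unit, 0)
                    terminal = [
                        (s, n)
                        for s, n in runs
                        if n >= min_copies and s + n * u >= len(ext) - 2 * u
                    ]
                    if terminal:
                        key = (len(ext), ident)
                        if (
                            best is None
                            or key > (best[0], best[1])
                            or (key == (best[0], best[1]) and rid < best[2])
                        ):
                            best = (len(ext), ident, rid, ext)
            pos = read.find(seed, pos + 1)

    if best is None:
        log.info("no patch for %s:%s (no anchored telomeric read)", chrom, end)
        return genome, PatchReport(chrom, end, False, None, 0, 0.0)

    ext_len, ident, rid, ext = best
    patched_work = work + ext
    patched_seq = patched_work if end == "3p" else revcomp(patched_work)
    sequences = dict(genome.sequences)
    sequences[chrom] = patched_seq
    patched = Genome(sequences)
    post = detect_telomeres(patched, unit=unit, min_copies=min_copies)
    if not post.present(chrom, end):
        log.warning("patched %s:%s still lacks a detectable telomere", chrom, end)
    log.info("patched %s:%s with %s (+%d bp)", chrom, end, rid, ext_len)
    return patched, PatchReport(chrom, end, True, rid, ext_len, ident)
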