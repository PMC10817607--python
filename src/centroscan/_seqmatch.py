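"""Internal sequence-matching primitives.

Two primitives back several stages: frame-exact tandem-repeat run finding
(telomere arrays) and ungapped seed-and-extend local matching (rDNA units,
LTR monomers).  Both operate on plain uppercase DNA strings; N never
matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import revcomp


def _frame_mismatches(seq: str, unit: str) -> np.ndarray:
    """Mismatch count of the unit-length frame starting at every position."""
    n, u = len(seq), len(unit)
    m = n - u + 1
    if m <= 0:
        return np.zeros(0, dtype=np.int32)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    ub = np.frombuffer(unit.encode(), dtype=np.uint8)
    mism = np.zeros(m, dtype=np.int32)
    for j in range(u):
        mism += arr[j : j + m] != ub[j]
    return mism


def tandem_runs(
    seq: str, unit: str, max_mismatch: int
) -> list[tuple[int, int]]:
    """Maximal tandem runs of ``unit`` in ``seq`` as ``(start, n_units)``.

    A run is a chain of abutting unit-length frames, each within the
    per-unit mismatch budget; insertions/deletions between frames break
    the chain.  Runs in every frame phase are reported.
    """
    u = len(unit)
    match = _frame_mismatches(seq, unit) <= max_mismatch
    if match.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    for phase in range(u):
        mr = match[phase::u].astype(np.int8)
        if mr.size == 0:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mr, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            runs.append((phase + s * u, int(e - s)))
    # suppress runs wholly contained in a longer run of another phase
    runs.sort(key=lambda r: (r[0], -r[1]))
    kept: list[tuple[int, int]] = []
    for start, n in runs:
        end = start + n * u
        if kept and start >= kept[-1][0] and end <= kept[-1][0] + kept[-1][1] * u:
            continue
        kept.append((start, n))
    return kept


def best_tandem_run(
    seq: str, unit: str, max_mismatch: int, window: int | None = None
) -> tuple[int, int]:
    """Longest tandem run ``(n_units, start)`` whose start lies in the window.

    Ties break toward the smallest start.  Returns ``(0, -1)`` when no run
    exists.
    """
    best_n, best_start = 0, -1
    for start, n in tandem_runs(seq, unit, max_mismatch):
        if window is not None and start >= window:
            continue
        if n > best_n:
            best_n, best_start = n, start
    return best_n, best_start


def max_tandem_copies(seq: str, unit: str, max_mismatch: int = 0) -> int:
    """Largest number of tandem unit copies anywhere in ``seq``."""
    n, _ = best_tandem_run(seq, unit, max_mismatch)
    return n


# ---------------------------------------------------------------------------
# Seed-and-extend ungapped local matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqHit:
    """An ungapped local match of a query against a subject sequence.

    ``q_start``/``q_end`` are coordinates on the strand-oriented query
    (the reverse complement for minus-strand hits), so two same-strand
    hits can be compared base-aligned through their query offsets.
    """

    start: int  # subject coordinates, 0-based half-open
    end: int
    strand: str
    identity: float
    q_cov: float  # matched fraction of the query length
    q_start: int = 0
    q_end: int = 0

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        return (self.end - self.start) * self.identity


def _best_segment(
    matches: np.ndarray, penalty: float
) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment (Kadane) of a +1/-penalty profile.

    Returns (start, end, n_matches); (0, 0, 0) if all-mismatch.
    """
    best_score = running = 0.0
    best = (0, 0)
    seg_start = 0
    for i, m in enumerate(matches):
        running += 1.0 if m else -penalty
        if running <= 0:
            running = 0.0
            seg_start = i + 1
        elif running > best_score:
            best_score = running
            best = (seg_start, i + 1)
    s, e = best
    return s, e, int(matches[s:e].sum())


def seed_extend_hits(
    subject: str,
    query: str,
    seed_k: int = 31,
    min_identity: float = 0.8,
    min_len: int = 100,
    step: int = 4,
    both_strands: bool = True,
) -> list[SeqHit]:
    """Find ungapped local matches of ``query`` in ``subject``.

    Exact ``seed_k``-mers anchor candidate diagonals; each diagonal is
    scored per-base and trimmed to its maximal-scoring segment, so
    truncated query copies are reported with proportionate ``q_cov``.
    """
    if not query:
        raise ValueError("empty query")
    if seed_k > len(query):
        raise ValueError("seed_k longer than query")
    penalty = min_identity / max(1e-9, 1.0 - min_identity) if min_identity < 1 else 1e9
    sub_arr = np.frombuffer(subject.encode(), dtype=np.uint8)
    hits: list[SeqHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        index: dict[str, list[int]] = {}
        for qpos in range(len(q) - seed_k + 1):
            index.setdefault(q[qpos : qpos + seed_k], []).append(qpos)
        offsets: set[int] = set()
        for p in range(0, len(subject) - seed_k + 1, step):
            for qpos in index.get(subject[p : p + seed_k], ()):
                offsets.add(p - qpos)
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for off in sorted(offsets):
            s0, s1 = max(off, 0), min(off + len(q), len(subject))
            if s1 - s0 < min_len:
                continue
            window = sub_arr[s0:s1]
            qwin = q_arr[s0 - off : s1 - off]
            matches = window == qwin
            seg_s, seg_e, n_match = _best_segment(matches, penalty)
            seg_len = seg_e - seg_s
            if seg_len < min_len:
                continue
            identity = n_match / seg_len
            if identity < min_identity:
                continue
            hits.append(
                SeqHit(
                    start=s0 + seg_s,
                    end=s0 + seg_e,
                    strand=strand,
                    identity=identity,
                    q_cov=seg_len / len(query),
                    q_start=s0 + seg_s - off,
                    q_end=s0 + seg_e - off,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def reduce_overlapping_hits(hits: list[SeqHit]) -> list[SeqHit]:
    """Keep the best-scoring hit among mutually overlapping ones."""
    kept: list[SeqHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start, h.strand)):
        if all(hit.end <= k.start or k.end <= hit.start for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def identity_ungapped(a: str, b: str) -> float:
    """Fraction of matching positions over the shorter of two strings."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    aa = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    bb = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float((aa == bb).mean())
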