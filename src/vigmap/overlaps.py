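"""Negative-gap detection and terminal-overlap contig merging.

During scaffolding, a gap whose flanking-contig overhangs exceed the
expected insert size (or whose estimated size is negative) suggests the two
contigs actually overlap. The terminal windows of such pairs are aligned
(k-mer seeds choose the overlap offset, an edit-distance extension scores
it) and the contigs are merged when at least ``min_len`` bases align at
``min_ident`` identity (defaults 500 bp / 95%, identity = matches divided by
alignment columns). Contigs essentially contained in a longer contig
(coverage and identity both above 98% by default) are dropped as duplicates.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib

from vigmap.seqs import SequenceSet, revcomp

SEED_K = 21
TERMINAL_SLACK = 50  # bp; how close to the ends an overlap must reach

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class BridgeCandidate:
    left_id: str
    right_id: str
    expected_insert: int
    left_overhang: int
    right_overhang: int
    estimated_gap: int


@dataclass(frozen=True)
class OverlapResult:
    aligned_length: int  # alignment columns
    identity: float  # matches / alignment columns
    left_end_offset: int  # start of the aligned region within the left sequence
    right_start_offset: int  # end (exclusive) of the aligned region within right
    merged: bool
    cigar: str = ""


def find_negative_gaps(layout, inserts: dict[str, int]) -> list[BridgeCandidate]:
    """Scan a scaffold layout for gaps that imply overlapping contigs.

    ``layout`` rows are mappings with keys ``left_id, right_id, gap,
    left_overhang, right_overhang, library``; ``inserts`` maps library name
    to its expected insert size. A pair is a candidate when the two
    overhangs together exceed the expected insert, or the estimated gap is
    negative.
    """
    out = []
    for row in layout:
        insert = inserts[row["library"]]
        overhang = row["left_overhang"] + row["right_overhang"]
        if overhang > insert or row["gap"] < 0:
            out.append(
                BridgeCandidate(
                    row["left_id"], row["right_id"], insert,
                    row["left_overhang"], row["right_overhang"], row["gap"],
                )
            )
    return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(alignment columns, matches) from an edlib extended cigar."""
    cols = matches = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return cols, matches


def _best_diagonals(a: str, b: str, k: int = SEED_K, top: int = 3) -> list[int]:
    """Most-supported offsets d such that a[d + t] pairs with b[t]."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        index[b[j : j + k]].append(j)
    votes: Counter[int] = Counter()
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            votes[i - j] += 1
    bucket_best: dict[int, tuple[int, int]] = {}
    for d, v in votes.items():
        bucket = d // (2 * TERMINAL_SLACK)
        if bucket not in bucket_best or v > bucket_best[bucket][0]:
            bucket_best[bucket] = (v, d)
    ranked = sorted(bucket_best.values(), key=lambda t: (-t[0], t[1]))
    return [d for _, d in ranked[:top]]


def terminal_overlap(
    left_seq: str,
    right_seq: str,
    window: int = 10_000,
    min_len: int = 500,
    min_ident: float = 0.95,
) -> OverlapResult:
    """Align the terminal windows of two contigs and score the best
    suffix(left)-to-prefix(right) overlap.

    Exact ``k``-mer seeds between the last ``window`` bases of ``left`` and
    the first ``window`` bases of ``right`` vote for candidate offsets; each
    candidate is extended by semi-global edit-distance alignment anchored at
    the left suffix start and the right start (free right tail), which makes
    the alignment terminal-consistent by construction. ``merged`` is true
    when at least ``min_len`` columns align at ``min_ident`` identity.
    """
    a = left_seq[-window:].upper()
    b = right_seq[:window].upper()
    off_a = len(left_seq) - len(a)
    best: OverlapResult | None = None
    for d in _best_diagonals(a, b):
        if d < 0:
            continue  # overlap would start before the right contig's first base
        query = a[d:]
        if not query:
            continue
        res = edlib.align(query, b, mode="SHW", task="path")
        cols, matches = _cigar_stats(res["cigar"])
        if cols == 0:
            continue
        identity = matches / cols
        cand = OverlapResult(
            aligned_length=cols,
            identity=identity,
            left_end_offset=off_a + d,
            right_start_offset=res["locations"][0][1] + 1,
            merged=cols >= min_len and identity >= min_ident,
            cigar=res["cigar"],
        )
        if best is None or (cand.merged, cand.aligned_length * cand.identity) > (
            best.merged,
            best.aligned_length * best.identity,
        ):
            best = cand
    if best is None:
        return OverlapResult(0, 0.0, len(left_seq), 0, False)
    return best


def merge_pair(left_seq: str, right_seq: str, overlap: OverlapResult) -> str:
    """Join two contigs through a verified overlap.

    The junction is placed at the alignment midpoint: the left contig is
    taken up to the column-midpoint of the overlap and the right contig from
    the corresponding coordinate. For gap-free overlaps the merged length is
    ``len(left) + len(right) - aligned_length``.
    """
    if not overlap.merged:
        raise ValueError("overlap did not pass merge thresholds")
    half = overlap.aligned_length // 2
    q_used = t_used = cols = 0
    for num, op in _CIGAR_RE.findall(overlap.cigar):
        n = int(num)
        take = min(n, half - cols)
        if take <= 0:
            break
        if op in ("=", "X"):
            q_used += take
            t_used += take
        elif op == "I":
            q_used += take
        else:  # D
            t_used += take
        cols += take
    return left_seq[: overlap.left_end_offset + q_used] + right_seq[t_used:]


def drop_contained(
    seqs: SequenceSet,
    min_cov: float = 0.98,
    min_ident: float = 0.98,
    k: int = SEED_K,
) -> SequenceSet:
    """Remove sequences essentially contained in a longer sequence.

    A shared-k-mer screen nominates candidate (shorter, longer) pairs;
    nominations are verified by infix edit-distance alignment of the shorter
    sequence (both orientations) against the longer one. The shorter member
    is dropped when ``1 - dist/len(shorter) >= min_cov * min_ident`` (a
    combined coverage-times-identity budget: unaligned ends surface as
    terminal gaps in the distance). Of a mutually contained pair, the longer
    sequence always survives.
    """
    order = sorted(seqs.records, key=lambda r: (-len(r[1]), r[0]))
    threshold = min_cov * min_ident
    kept: list[tuple[str, str, set[str]]] = []  # (id, seq, kmer set)
    removed: set[str] = set()
    for sid, seq in order:
        qk = {seq[i : i + k] for i in range(0, max(1, len(seq) - k + 1), 25)}
        contained = False
        for _, tseq, tk in kept:
            if len(seq) > len(tseq):
                continue
            share = len(qk & tk) / max(1, len(qk))
            rc_seq = revcomp(seq)
            if share < 0.3:
                rk = {rc_seq[i : i + k] for i in range(0, max(1, len(seq) - k + 1), 25)}
                if len(rk & tk) / max(1, len(rk)) < 0.3:
                    continue
            for q in (seq, rc_seq):
                dist = edlib.align(q, tseq, mode="HW", task="distance")["editDistance"]
                if 1.0 - dist / len(q) >= threshold:
                    contained = True
                    break
            if contained:
                break
        if contained:
            removed.add(sid)
        else:
            tk_full = {seq[i : i + k] for i in range(len(seq) - k + 1)} if len(seq) >= k else {seq}
            kept.append((sid, seq, tk_full))
    return SequenceSet(
        [(sid, s) for sid, s in seqs.records if sid not in removed], seqs.kind
    )
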