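"""Paired-read overlap merging and length filtering.

Forward and reverse mates are collapsed into single fragments when they
overlap by at least ``min_overlap`` bases (default 11); unmerged pairs
are discarded and merged reads shorter than ``min_length`` (default 30)
are filtered out.  Adapter read-through is removed implicitly by the
merge geometry: when the mates overhang each other the merged read is
restricted to the overlapping (fragment) region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import decode, encode, revcomp_codes


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_length: int
    source: str = "merged"


@dataclass
class MergeParams:
    min_overlap: int = 11
    min_length: int = 30
    max_mismatch_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_overlap < 1 or self.min_length < 1:
            raise ValueError("min_overlap and min_length must be >= 1")


@dataclass
class Rejection:
    id: str
    reason: str


def _candidate_offsets(s1: np.ndarray, s2rc: np.ndarray, min_overlap: int) -> Iterator[int]:
    """Offsets of mate2(rc) start relative to mate1 start, best-first candidates.

    Seeds exact 16-mer matches in both directions (fast path for
    error-free overlaps), then falls back to the exhaustive offset range.
    """
    n1, n2 = len(s1), len(s2rc)
    seen: set[int] = set()
    k = min(16, n1, n2)
    t1, t2 = decode(s1), decode(s2rc)
    for anchor, hay, sign in ((t2[:k], t1, 1), (t1[:k], t2, -1)):
        pos = hay.find(anchor)
        while pos != -1:
            off = sign * pos
            if off not in seen:
                seen.add(off)
                yield off
            pos = hay.find(anchor, pos + 1)
    for off in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        if off not in seen:
            yield off


def merge_pair(pair: ReadPair, params: MergeParams | None = None) -> MergedRead | Rejection:
    """Merge one pair by scanning overlap offsets of mate1 vs revcomp(mate2).

    The best overlap (matches minus mismatches, ties toward longer
    overlap) of length >= min_overlap and mismatch fraction <=
    max_mismatch_fraction is accepted; in the overlap the
    higher-quality base wins (ties: mate1).  N bases count as
    mismatches.  Read-through geometry (mate2 start left of mate1
    start) restricts the merged read to the overlap, which drops
    adapters.
    """
    params = params or MergeParams()
    s1, s2rc = encode(pair.seq1), revcomp_codes(encode(pair.seq2))
    q1 = np.frombuffer(pair.qual1.encode(), dtype=np.uint8).astype(np.int16) - 33
    q2rc = (np.frombuffer(pair.qual2.encode(), dtype=np.uint8).astype(np.int16) - 33)[::-1]
    n1, n2 = len(s1), len(s2rc)
    if min(n1, n2) < params.min_overlap:
        return Rejection(pair.id, "unmerged")

    best: tuple[float, int, int] | None = None  # (score, ov_len, offset)
    for off in _candidate_offsets(s1, s2rc, params.min_overlap):
        a0, a1 = max(0, off), min(n1, off + n2)
        ov = a1 - a0
        if ov < params.min_overlap:
            continue
        w1 = s1[a0:a1]
        w2 = s2rc[a0 - off : a1 - off]
        mism = int(np.count_nonzero((w1 != w2) | (w1 > 3) | (w2 > 3)))
        if mism > params.max_mismatch_fraction * ov:
            continue
        score = (ov - mism) - mism
        if best is None or (score, ov) > (best[0], best[1]):
            best = (score, ov, off)
            if mism == 0 and ov == min(n1, n2):
                break  # cannot be beaten
    if best is None:
        return Rejection(pair.id, "unmerged")
    _, ov, off = best

    a0, a1 = max(0, off), min(n1, off + n2)
    take2 = q2rc[a0 - off : a1 - off] > q1[a0:a1]
    ov_seq = np.where(take2, s2rc[a0 - off : a1 - off], s1[a0:a1])
    ov_q = np.where(take2, q2rc[a0 - off : a1 - off], q1[a0:a1])
    if off >= 0:
        seq = np.concatenate([s1[:a0], ov_seq, s2rc[a1 - off :]])
        qual = np.concatenate([q1[:a0], ov_q, q2rc[a1 - off :]])
    else:
        # read-through: mates overhang into adapter on both sides; keep overlap only
        seq, qual = ov_seq, ov_q
    return MergedRead(
        id=pair.id,
        seq=decode(seq),
        qual="".join(chr(int(q) + 33) for q in qual),
        overlap_length=ov,
    )


def merge_pairs(pairs: Iterable[ReadPair], params: MergeParams | None = None
                ) -> tuple[list[MergedRead], Counter]:
    """Merge many pairs; returns (merged reads, per-reason discard counts)."""
    params = params or MergeParams()
    merged: list[MergedRead] = []
    stats: Counter = Counter(total_pairs=0, merged=0, discarded_unmerged=0)
    for pair in pairs:
        stats["total_pairs"] += 1
        result = merge_pair(pair, params)
        if isinstance(result, MergedRead):
            merged.append(result)
            stats["merged"] += 1
        else:
            stats["discarded_" + result.reason] += 1
    return merged, stats


def filter_merged(reads: list[MergedRead], params: MergeParams | None = None
                  ) -> tuple[list[MergedRead], Counter]:
    """Retain merged reads of length >= min_length; log discards."""
    params = params or MergeParams()
    retained = [r for r in reads if len(r.seq) >= params.min_length]
    log = Counter(discarded_short=len(reads) - len(retained), retained=len(retained))
    return retained, log


def read_fastq_pairs(path_r1: str, path_r2: str) -> Iterator[ReadPair]:
    """Stream pairs from two FASTQ files (ids must pair up in order)."""
    with open(path_r1) as f1, open(path_r2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            base1, base2 = id1.split()[0], id2.split()[0]
            if base1.rstrip("/12") != base2.rstrip("/12"):
                raise ValueError(f"unpaired reads: {id1} vs {id2}")
            yield ReadPair(base1, s1, s2, q1, q2)


def write_merged_fastq(reads: Iterable[MergedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def merge_files(path_r1: str, path_r2: str, out_fastq: str,
                params: MergeParams | None = None) -> Counter:
    """File-level merge+filter: R1/R2 FASTQ in, merged FASTQ out, stats returned."""
    params = params or MergeParams()
    merged, stats = merge_pairs(read_fastq_pairs(path_r1, path_r2), params)
    retained, log = filter_merged(merged, params)
    stats.update(log)
    write_merged_fastq(retained, out_fastq)
    return stats
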