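"""Iterative reference-guided mitogenome assembly.

Reads are placed on the (circular, doubled) reference by seeded gapless
diagonal scoring with damage-aware penalties: terminal C->T / G->A
mismatches — the deamination signature of authentic ancient reads — are
discounted by q**p with p the distance from the relevant read terminus,
so heavily deaminated reads still map while contaminant reads, whose
mismatches are spread over all twelve substitution types, are rejected
by the score threshold.  After duplicate collapse a >=3-fold-coverage
majority consensus is called, the consensus replaces the reference, and
mapping repeats until the consensus is stable — so a distant starting
reference (e.g. a congeneric mitogenome) converges onto the sample's
own sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import A, C, G, N, T, decode, encode, revcomp_codes
from .merge import MergedRead
from .simulate import ReferenceGenome

# purine/pyrimidine collapse: C->T and G->A deamination is invisible in
# this alphabet, so masked seeds survive arbitrary damage
_PUPY = np.array([0, 1, 0, 1, 2, 2], dtype=np.int8)  # A,G -> 0; C,T -> 1


@dataclass
class MapParams:
    match: float = 1.0
    mismatch: float = -1.0
    damage_decay: float = 0.5       # q in the q**p terminal discount
    min_score_frac: float = 0.5     # unmapped below this fraction of read length
    seed_k: int = 16
    masked_seed_k: int = 24
    exhaustive_ref_len: int = 2000  # small references: score every diagonal


@dataclass
class AlignmentRecord:
    """A gapless placement of a read on the circular reference.

    ``ref_start < ref_end`` unwrapped (``ref_end`` may exceed the genome
    length for origin-spanning reads); ``codes``/``quals`` are stored in
    reference sense.
    """

    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str
    score: float
    codes: np.ndarray = field(repr=False)
    quals: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


class ReferenceIndex:
    """Doubled-sequence k-mer index of a circular reference."""

    def __init__(self, ref: ReferenceGenome, params: MapParams | None = None):
        if len(ref) == 0:
            raise ValueError("empty reference")
        self.params = params or MapParams()
        self.length = len(ref)
        self.codes = ref.codes
        self.doubled = np.concatenate([self.codes, self.codes])
        self._exact = self._build(self.doubled, self.params.seed_k, 4)
        self._masked = self._build(_PUPY[self.doubled], self.params.masked_seed_k, 2)

    @staticmethod
    def _build(codes: np.ndarray, k: int, alphabet: int) -> dict[int, np.ndarray]:
        if len(codes) < k:
            return {}
        mult = alphabet ** np.arange(k, dtype=np.int64)
        keys = sliding_window_view(codes.astype(np.int64), k) @ mult
        index: dict[int, list[int]] = {}
        for pos, key in enumerate(keys.tolist()):
            index.setdefault(key, []).append(pos)
        return {k_: np.asarray(v) for k_, v in index.items()}

    def _seed_diagonals(self, codes: np.ndarray) -> np.ndarray:
        m = len(codes)
        diags: set[int] = set()
        for index, k, alphabet, view in (
            (self._exact, self.params.seed_k, 4, codes),
            (self._masked, self.params.masked_seed_k, 2, _PUPY[codes]),
        ):
            if m < k or not index:
                continue
            mult = alphabet ** np.arange(k, dtype=np.int64)
            step = max(1, (m - k) // 7) if m > k else 1
            offsets = range(0, m - k + 1, step)
            for off in offsets:
                window = view[off : off + k].astype(np.int64)
                if window.max() > 3:      # contains N
                    continue
                hits = index.get(int(window @ mult))
                if hits is not None:
                    for h in hits[:20]:
                        diags.add(int(h - off) % self.length)
        return np.fromiter(diags, dtype=np.int64) if diags else np.empty(0, dtype=np.int64)

    def score_diagonals(self, codes: np.ndarray, starts: np.ndarray,
                        damage_aware: bool) -> np.ndarray:
        """Gapless damage-aware score of ``codes`` at each reference start."""
        p = self.params
        m = len(codes)
        windows = self.doubled[starts[:, None] + np.arange(m)]
        mism = windows != codes
        cost = np.where(mism, p.mismatch, p.match)
        if damage_aware:
            pos = np.arange(1, m + 1, dtype=float)
            disc_ct = p.mismatch * p.damage_decay**pos          # 5' C->T
            disc_ga = p.mismatch * p.damage_decay**pos[::-1]    # 3' G->A
            ct = mism & (windows == C) & (codes == T)
            ga = mism & (windows == G) & (codes == A)
            cost = np.where(ct, disc_ct, np.where(ga, disc_ga, cost))
        cost = np.where((windows > 3) | (codes > 3), p.mismatch, cost)  # N never matches
        return cost.sum(axis=1)

    def map_read(self, codes: np.ndarray, quals: np.ndarray, read_id: str,
                 damage_aware: bool = True) -> AlignmentRecord | None:
        m = len(codes)
        if m == 0 or m > self.length:
            return None
        best: tuple[float, int, str] | None = None
        for strand, oriented in (("+", codes), ("-", revcomp_codes(codes))):
            if self.length <= self.params.exhaustive_ref_len:
                starts = np.arange(self.length)
            else:
                starts = self._seed_diagonals(oriented)
                if len(starts) == 0:
                    continue
            scores = self.score_diagonals(oriented, starts, damage_aware)
            i = int(np.argmax(scores))
            if best is None or scores[i] > best[0]:
                best = (float(scores[i]), int(starts[i]), strand)
        if best is None or best[0] < self.params.min_score_frac * m:
            return None
        score, start, strand = best
        ref_codes = codes if strand == "+" else revcomp_codes(codes)
        ref_quals = quals if strand == "+" else quals[::-1]
        return AlignmentRecord(read_id, start, start + m, strand, f"{m}M",
                               score, ref_codes, ref_quals)


def map_reads(reads: Sequence[MergedRead], ref: ReferenceGenome,
              damage_aware: bool = True, params: MapParams | None = None
              ) -> list[AlignmentRecord]:
    """Map length-filtered merged reads to a circular reference."""
    index = ReferenceIndex(ref, params)
    out = []
    for r in reads:
        codes = encode(r.seq)
        quals = np.frombuffer(r.qual.encode(), dtype=np.uint8).astype(np.int16) - 33
        rec = index.map_read(codes, quals, r.id, damage_aware)
        if rec is not None:
            out.append(rec)
    return out


def remove_duplicates(alignments: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse alignments sharing (ref_start, ref_end, strand).

    The representative is the copy with the highest summed base quality
    (first seen wins ties), matching the "unique mapped reads"
    semantics of coordinate-based duplicate removal.
    """
    best: dict[tuple[int, int, str], tuple[float, AlignmentRecord]] = {}
    for rec in alignments:
        key = (rec.ref_start, rec.ref_end, rec.strand)
        qsum = float(rec.quals.sum())
        if key not in best or qsum > best[key][0]:
            best[key] = (qsum, rec)
    return [rec for _, rec in best.values()]


@dataclass
class ConsensusParams:
    min_coverage: int = 3
    majority_fraction: float = 0.5
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage >= 1 required")


def call_consensus(alignments: Sequence[AlignmentRecord], ref_length: int,
                   params: ConsensusParams | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Majority consensus from a duplicate-free pileup.

    Returns (consensus codes with N below threshold/tie, coverage
    track).  Read N bases contribute to neither counts nor coverage.
    """
    params = params or ConsensusParams()
    counts = np.zeros((ref_length, 4), dtype=np.int32)
    if alignments:
        pos_chunks, base_chunks = [], []
        for rec in alignments:
            pos_chunks.append(np.arange(rec.ref_start, rec.ref_end) % ref_length)
            base_chunks.append(rec.codes)
        pos = np.concatenate(pos_chunks)
        bases = np.concatenate(base_chunks)
        ok = bases < 4
        np.add.at(counts, (pos[ok], bases[ok].astype(np.int64)), 1)
    coverage = counts.sum(axis=1)
    top = counts.max(axis=1)
    winner = counts.argmax(axis=1).astype(np.int8)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(coverage > 0, top / np.maximum(coverage, 1), 0.0)
    consensus = np.where(
        (coverage >= params.min_coverage) & ~tie & (frac >= params.majority_fraction),
        winner, np.int8(N),
    ).astype(np.int8)
    return consensus, coverage


@dataclass
class AssemblyResult:
    consensus: str
    coverage: np.ndarray
    unique_fragments: int
    mapped_fragments: int
    iterations: int
    fraction_covered: float        # fraction of positions at >= min_coverage
    mean_unique_coverage: float
    mean_read_length: float
    failed: bool = False

    @property
    def consensus_codes(self) -> np.ndarray:
        return encode(self.consensus)


def iterate_assembly(reads: Sequence[MergedRead], initial_ref: ReferenceGenome,
                     params: ConsensusParams | None = None,
                     map_params: MapParams | None = None,
                     damage_aware: bool = True) -> AssemblyResult:
    """Map -> dedup -> consensus, re-mapping to each round's consensus.

    N positions in the consensus are replaced by the previous round's
    reference base for mapping purposes only; the returned consensus
    keeps its Ns.  Stops at a byte-identical consensus or after
    ``max_iterations`` rounds.
    """
    params = params or ConsensusParams()
    ref_length = len(initial_ref)
    mapping_codes = initial_ref.codes
    prev_consensus: np.ndarray | None = None
    consensus = np.full(ref_length, N, dtype=np.int8)
    coverage = np.zeros(ref_length, dtype=np.int32)
    unique: list[AlignmentRecord] = []
    mapped_n = 0
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        mapping_ref = ReferenceGenome(initial_ref.id, decode(mapping_codes),
                                      circular=initial_ref.circular)
        alignments = map_reads(reads, mapping_ref, damage_aware, map_params)
        if iterations == 1 and not alignments:
            return AssemblyResult("N" * ref_length, coverage, 0, 0, 1, 0.0, 0.0, 0.0,
                                  failed=True)
        mapped_n = len(alignments)
        unique = remove_duplicates(alignments)
        consensus, coverage = call_consensus(unique, ref_length, params)
        if prev_consensus is not None and np.array_equal(consensus, prev_consensus):
            break
        prev_consensus = consensus
        mapping_codes = np.where(consensus == N, mapping_codes, consensus)
    lengths = [rec.length for rec in unique]
    return AssemblyResult(
        consensus=decode(consensus),
        coverage=coverage,
        unique_fragments=len(unique),
        mapped_fragments=mapped_n,
        iterations=iterations,
        fraction_covered=float((coverage >= params.min_coverage).mean()),
        mean_unique_coverage=float(coverage.mean()),
        mean_read_length=float(np.mean(lengths)) if lengths else 0.0,
    )
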