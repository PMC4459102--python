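"""Mapper, duplicate removal, consensus calling and iterative assembly."""

import numpy as np
import pytest

from megalomito._seq import decode, encode, revcomp
from megalomito.assemble import (AlignmentRecord, ConsensusParams,
                                 ReferenceIndex, call_consensus,
                                 iterate_assembly, map_reads,
                                 remove_duplicates)
from megalomito.merge import MergedRead
from megalomito.simulate import (FragmentationModel,
                                 ReferenceGenome, simulate_damaged_fragments,
                                 simulate_reference)


def _read(seq: str, rid: str = "r") -> MergedRead:
    return MergedRead(rid, seq, "F" * len(seq), 0)


def _rec(start, end, strand="+", qual=37, length=None) -> AlignmentRecord:
    n = length if length is not None else end - start
    return AlignmentRecord("x", start, end, strand, f"{n}M", float(n),
                           np.zeros(n, dtype=np.int8),
                           np.full(n, qual, dtype=np.int16))


class TestMapper:
    def test_exact_substring_maps_at_true_locus(self, mito_ref):
        read = _read(mito_ref.sequence[500:540])
        [rec] = map_reads([read], mito_ref, damage_aware=False)
        assert (rec.ref_start, rec.ref_end, rec.strand) == (500, 540, "+")
        assert rec.cigar == "40M"

    def test_reverse_strand_read_maps(self, mito_ref):
        read = _read(revcomp(mito_ref.sequence[800:860]))
        [rec] = map_reads([read], mito_ref)
        assert (rec.ref_start, rec.ref_end, rec.strand) == (800, 860, "-")

    def test_origin_spanning_read_wraps(self, mito_ref):
        doubled = mito_ref.sequence * 2
        read = _read(doubled[16480:16530])
        [rec] = map_reads([read], mito_ref)
        assert (rec.ref_start, rec.ref_end) == (16480, 16530)

    def test_damage_aware_scores_terminal_ct_higher(self, mito_ref):
        start = mito_ref.sequence.index("C", 300)  # window starting on a C
        seq = mito_ref.sequence[start:start + 40]
        damaged = "T" + seq[1:]                    # 5'-terminal C->T
        index = ReferenceIndex(mito_ref)
        codes = encode(damaged)
        starts = np.array([start])
        aware = index.score_diagonals(codes, starts, damage_aware=True)[0]
        naive = index.score_diagonals(codes, starts, damage_aware=False)[0]
        assert aware > naive

    def test_contaminant_read_unmapped(self, mito_ref):
        rng = np.random.default_rng(8)
        junk = "".join(rng.choice(list("ACGT"), size=60))
        assert map_reads([_read(junk)], mito_ref) == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceGenome("empty", "")

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_oracle_equivalence(self, seed):
        """Best locus equals a brute-force all-offset scan on tiny inputs."""
        rng = np.random.default_rng(seed)
        ref = simulate_reference(200, 0.45, seed=seed + 50)
        start = int(rng.integers(0, 200))
        length = int(rng.integers(20, 31))
        read_seq = decode(ref.fragment_codes(start, start + length, "+"))
        # introduce one random substitution
        i = int(rng.integers(0, length))
        alt = "ACGT"[(encode(read_seq)[i] + 1) % 4]
        read_seq = read_seq[:i] + alt + read_seq[i + 1:]

        [rec] = map_reads([_read(read_seq)], ref, damage_aware=False)

        # brute force: score every start on both strands, python loop
        doubled = ref.sequence * 2
        best = None
        for strand, s in (("+", read_seq), ("-", revcomp(read_seq))):
            for off in range(200):
                window = doubled[off:off + length]
                score = sum(1 if a == b else -1 for a, b in zip(s, window))
                if best is None or score > best[0]:
                    best = (score, off, strand)
        assert (rec.score, rec.ref_start, rec.strand) == best


class TestDuplicates:
    def test_copies_collapse_to_one(self):
        recs = [_rec(100, 160) for _ in range(5)]
        assert len(remove_duplicates(recs)) == 1

    def test_distinct_endpoints_retained(self):
        assert len(remove_duplicates([_rec(100, 160), _rec(100, 161)])) == 2

    def test_strand_distinguishes(self):
        assert len(remove_duplicates([_rec(0, 50, "+"), _rec(0, 50, "-")])) == 2

    def test_highest_quality_copy_survives(self):
        low, high = _rec(10, 50, qual=10), _rec(10, 50, qual=40)
        [kept] = remove_duplicates([low, high])
        assert kept is high

    def test_unique_fraction_matches_occupancy_model(self, small_ref):
        """Random draws from a finite coordinate space: unique count follows
        the occupancy expectation m*(1 - (1-1/m)^n)."""
        rng = np.random.default_rng(11)
        m = 400  # distinct (start, end) coordinate pairs available
        starts = rng.integers(0, m, size=2000)
        recs = [_rec(int(s), int(s) + 60) for s in starts]
        unique = len(remove_duplicates(recs))
        expected = m * (1 - (1 - 1 / m) ** 2000)
        assert abs(unique - expected) < 4 * np.sqrt(m)


class TestConsensus:
    def _pileup(self, column_bases, ref_length=1):
        recs = []
        for i, b in enumerate(column_bases):
            codes = encode(b)
            recs.append(AlignmentRecord(f"p{i}", 0, 1, "+", "1M", 1.0, codes,
                                        np.full(1, 37, dtype=np.int16)))
        return recs

    def test_three_fold_threshold(self):
        cons, cov = call_consensus(self._pileup("AAA"), 1, ConsensusParams())
        assert decode(cons) == "A" and cov[0] == 3
        cons, cov = call_consensus(self._pileup("AA"), 1, ConsensusParams())
        assert decode(cons) == "N" and cov[0] == 2

    def test_tie_gives_n(self):
        cons, _ = call_consensus(self._pileup("AATT"), 1, ConsensusParams())
        assert decode(cons) == "N"

    def test_tiled_error_free_reads_recover_reference(self, small_ref):
        reads = []
        for start in range(0, 1000, 10):
            for offset in (0, 3, 7):
                s, e = start + offset, start + offset + 40
                codes = small_ref.fragment_codes(s, e, "+")
                reads.append(AlignmentRecord(f"t{s}", s, e, "+", "40M", 40.0,
                                             codes, np.full(40, 37, np.int16)))
        cons, cov = call_consensus(reads, 1000, ConsensusParams())
        covered = cov >= 3
        assert covered.mean() > 0.95
        assert np.array_equal(cons[covered], small_ref.codes[covered])


class TestIterativeAssembly:
    def _simulated_reads(self, ref, coverage=30, seed=2, damage=None):
        frag = FragmentationModel(mean_length=60, coverage_target=coverage)
        _, seqs, _ = simulate_damaged_fragments(ref, frag, damage, seed)
        return [_read(decode(s), f"r{i}") for i, s in enumerate(seqs)]

    def test_divergent_reference_converges_to_truth(self, small_ref):
        """Reads from a genome 5% divergent from the mapping reference:
        iteration recovers the true genome; a single pass does not."""
        rng = np.random.default_rng(33)
        truth_codes = small_ref.codes.copy()
        div = rng.choice(1000, size=100, replace=False)  # 10% divergence
        truth_codes[div] = (truth_codes[div] + rng.integers(1, 4, size=100)) % 4
        truth = ReferenceGenome("truth", decode(truth_codes))
        reads = self._simulated_reads(truth, coverage=30)

        single = iterate_assembly(reads, small_ref,
                                  ConsensusParams(max_iterations=1))
        full = iterate_assembly(reads, small_ref, ConsensusParams())
        well = full.coverage >= 3
        assert np.array_equal(full.consensus_codes[well], truth_codes[well])
        # re-mapping to the consensus recovers reads the divergent start
        # reference rejected, so completeness does not drop
        assert full.fraction_covered >= single.fraction_covered
        assert full.iterations > 1

    def test_fixed_point_on_own_reference(self, small_ref):
        reads = self._simulated_reads(small_ref, coverage=20, seed=4)
        result = iterate_assembly(reads, small_ref, ConsensusParams())
        well = result.coverage >= 3
        assert np.array_equal(result.consensus_codes[well], small_ref.codes[well])
        assert result.iterations <= 3  # converges almost immediately

    def test_no_mapped_reads_is_explicit_failure(self, small_ref):
        rng = np.random.default_rng(9)
        junk = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
        result = iterate_assembly([_read(s, f"j{i}") for i, s in enumerate(junk)],
                                  small_ref)
        assert result.failed and set(result.consensus) == {"N"}

    def test_hamming_distance_non_increasing_over_seeds(self, small_ref):
        """Iteration moves the consensus toward the truth (checked over
        many seeds; the final round is never worse than round 1)."""
        violations = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            truth_codes = small_ref.codes.copy()
            div = rng.choice(1000, size=30, replace=False)
            truth_codes[div] = (truth_codes[div] + rng.integers(1, 4, size=30)) % 4
            truth = ReferenceGenome("t", decode(truth_codes))
            reads = self._simulated_reads(truth, coverage=15, seed=seed)
            one = iterate_assembly(reads, small_ref, ConsensusParams(max_iterations=1))
            full = iterate_assembly(reads, small_ref, ConsensusParams())
            d1 = ((one.consensus_codes != truth_codes) & (one.coverage >= 3)).sum()
            d2 = ((full.consensus_codes != truth_codes) & (full.coverage >= 3)).sum()
            if d2 > d1:
                violations += 1
        assert violations == 0

    def test_coverage_conservation(self, small_ref):
        reads = self._simulated_reads(small_ref, coverage=10, seed=6)
        result = iterate_assembly(reads, small_ref)
        alns = remove_duplicates(map_reads(reads, small_ref))
        total_bases = sum(r.length for r in alns)
        assert result.coverage.sum() == total_bases
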