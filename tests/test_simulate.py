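"""Synthetic-data generator: references, fragments, damage, FASTQ, isotopes."""

import math

import numpy as np
import pytest
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from megalomito._seq import C, G, T, decode, encode
from megalomito.simulate import (DamageModel, FragmentationModel, IsotopeGroup,
                                 IsotopeSimSpec, apply_damage,
                                 default_isotope_spec, emit_fastq_pairs,
                                 simulate_alignment_on_tree,
                                 simulate_damaged_fragments, simulate_fragments,
                                 simulate_isotope_table, simulate_reference)
from megalomito.phylo.model import PhyloModel
from megalomito.phylo.tree import Node


class TestReference:
    def test_length_and_gc(self):
        ref = simulate_reference(16500, 0.4, seed=1)
        assert len(ref.sequence) == 16500
        gc = sum(b in "GC" for b in ref.sequence) / 16500
        assert abs(gc - 0.4) < 0.02  # binomial noise at n=16500

    def test_degenerate_gc_zero_gives_at_only(self):
        ref = simulate_reference(100, 0.0, seed=1)
        assert set(ref.sequence) <= {"A", "T"}

    def test_seed_determinism(self):
        a = simulate_reference(1000, 0.5, seed=7)
        b = simulate_reference(1000, 0.5, seed=7)
        assert a.sequence == b.sequence

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_reference(50, 0.4, seed=1)
        with pytest.raises(ValueError):
            simulate_reference(1000, 1.5, seed=1)


class TestFragments:
    def test_count_and_mean_length_match_coverage_target(self, mito_ref):
        frag = FragmentationModel(mean_length=60, coverage_target=30)
        frags = simulate_fragments(mito_ref, frag, seed=1)
        # expectation: coverage * L / mean_length fragments
        assert abs(len(frags) - 30 * 16500 / 60) <= 1
        mean_len = np.mean([e - s for s, e, _ in frags])
        assert abs(mean_len - 60) / 60 < 0.05

    def test_wraparound_fragment_decodes(self, small_ref):
        codes = small_ref.fragment_codes(990, 1030, "+")
        assert len(codes) == 40
        assert decode(codes) == (small_ref.sequence + small_ref.sequence)[990:1030]

    def test_seed_determinism(self, small_ref):
        frag = FragmentationModel(coverage_target=5)
        assert simulate_fragments(small_ref, frag, 3) == simulate_fragments(
            small_ref, frag, 3)

    def test_mean_below_min_rejected(self):
        with pytest.raises(ValueError):
            FragmentationModel(mean_length=10, min_length=30)


class TestDamage:
    def test_zero_damage_identity(self, small_ref, rng):
        codes = small_ref.fragment_codes(0, 60, "+")
        model = DamageModel(overhang_decay=0.5, delta_ss=0.0, delta_ds=0.0)
        out, truth = apply_damage(codes, model, rng)
        assert np.array_equal(out, codes)
        assert truth == []

    def test_only_ct_and_ga_changes(self, small_ref, rng):
        codes = small_ref.fragment_codes(0, 80, "+")
        model = DamageModel(overhang_decay=0.9, delta_ss=1.0, delta_ds=0.05)
        out, truth = apply_damage(codes, model, rng)
        changed = np.flatnonzero(out != codes)
        assert set(changed) == {p for p, _ in truth}
        for p in changed:
            assert (codes[p], out[p]) in {(C, T), (G, 0)}  # C->T or G->A

    def test_double_strand_cap_is_half(self, small_ref):
        """delta_ss=1, overhang everywhere, both strands: pooled 5' C->T -> 50%."""
        model = DamageModel(overhang_decay=1.0, delta_ss=1.0, both_strands=True)
        assert model.expected_ct_frequency(1) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        start = next(i for i in range(1000) if small_ref.codes[i] == C)
        codes = small_ref.fragment_codes(start, start + 60, "+")
        hits = sum(apply_damage(codes, model, rng)[0][0] == T for _ in range(20000))
        assert abs(hits / 20000 - 0.5) < 0.01

    def test_single_strand_protocol_reaches_full_deamination(self, small_ref):
        model = DamageModel(overhang_decay=1.0, delta_ss=1.0, both_strands=False)
        rng = np.random.default_rng(0)
        start = next(i for i in range(1000) if small_ref.codes[i] == C)
        codes = small_ref.fragment_codes(start, start + 60, "+")
        for _ in range(200):
            out, _ = apply_damage(codes, model, rng)
            assert out[0] == T

    def test_for_terminal_rate_closed_form(self):
        for rate in (0.27, 0.49, 0.25):
            model = DamageModel.for_terminal_rate(rate)
            assert model.expected_ct_frequency(1) == pytest.approx(rate)
        with pytest.raises(ValueError):
            DamageModel.for_terminal_rate(0.6)  # beyond the 50% protocol cap


class TestFastqEmission:
    def test_pairs_parse_and_adapter_geometry(self, small_ref, tmp_path):
        frag = FragmentationModel(mean_length=60, coverage_target=2)
        coords, seqs, _ = simulate_damaged_fragments(small_ref, frag, None, 5,
                                                     n_fragments=10)
        r1, r2 = str(tmp_path / "r1.fastq"), str(tmp_path / "r2.fastq")
        n = emit_fastq_pairs(seqs, 100, r1, r2, seed=1)
        assert n == 10
        recs1 = list(SeqIO.parse(r1, "fastq"))
        recs2 = list(SeqIO.parse(r2, "fastq"))
        assert len(recs1) == len(recs2) == 10
        assert [r.id for r in recs1] == [r.id for r in recs2]
        for rec, codes in zip(recs1, seqs):
            frag_seq = decode(codes)
            # error-free mate 1 starts with the fragment, then adapter
            assert str(rec.seq).startswith(frag_seq[:100])
            if len(frag_seq) < 100:
                assert str(rec.seq)[len(frag_seq):].startswith("AGATCGG"[:100 - len(frag_seq)])

    def test_mate2_is_reverse_complement(self, small_ref, tmp_path):
        codes = [small_ref.fragment_codes(0, 100, "+")]
        r1, r2 = str(tmp_path / "a.fastq"), str(tmp_path / "b.fastq")
        emit_fastq_pairs(codes, 100, r1, r2, seed=1)
        with open(r1) as f1, open(r2) as f2:
            (_, s1, _), = FastqGeneralIterator(f1)
            (_, s2, _), = FastqGeneralIterator(f2)
        assert encode(s2).tolist() == [3 - c for c in encode(s1)[::-1]]


class TestAlignmentOnTree:
    def test_zero_branch_lengths_identical_taxa(self):
        tree = Node.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = simulate_alignment_on_tree(tree, PhyloModel.jc(alpha=None), 200, 1)
        assert all(aln.sequence(t) == aln.sequence("A") for t in "BCD")

    def test_jc_pairwise_divergence_closed_form(self):
        t = 0.3
        tree = Node.from_newick(f"(A:{t / 2},B:{t / 2});")
        aln = simulate_alignment_on_tree(tree, PhyloModel.jc(alpha=None), 100000, 2)
        diff = np.mean(aln.row("A") != aln.row("B"))
        expected = 0.75 * (1 - math.exp(-4 * t / 3))
        assert abs(diff - expected) < 0.005

    def test_seed_determinism(self):
        tree = Node.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        model = PhyloModel.jc(alpha=0.5, n_categories=4)
        a = simulate_alignment_on_tree(tree, model, 500, 9)
        b = simulate_alignment_on_tree(tree, model, 500, 9)
        assert np.array_equal(a.matrix, b.matrix)


class TestIsotopeSimulation:
    def test_zero_sd_zero_noise_constant(self):
        spec = IsotopeSimSpec(
            groups=[IsotopeGroup("Rangifer", "pre-LGM", -18.0, 3.0, 0.0, 0.0, 5)],
            noise_d13c=0.0, noise_d15n=0.0)
        df = simulate_isotope_table(spec, 1)
        assert (df["d13C"] == -18.0).all() and (df["d15N"] == 3.0).all()

    def test_invalid_cn_fraction_binomial(self):
        spec = IsotopeSimSpec(
            groups=[IsotopeGroup("Cervus", "pre-LGM", -20.0, 4.0, 0.5, 0.5, 1000)],
            invalid_cn_fraction=0.1)
        df = simulate_isotope_table(spec, 3)
        cn = (df["pctC"] / 12.011) / (df["pctN"] / 14.007)
        n_bad = ((cn < 2.9) | (cn > 3.6)).sum()
        assert abs(n_bad - 100) < 3 * math.sqrt(1000 * 0.1 * 0.9)

    def test_determinism_and_empty_groups(self):
        spec = default_isotope_spec()
        assert simulate_isotope_table(spec, 5).equals(simulate_isotope_table(spec, 5))
        with pytest.raises(ValueError):
            simulate_isotope_table(IsotopeSimSpec(groups=[]), 1)
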