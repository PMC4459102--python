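"""Canned study-condition workflows built from the pipeline stages.

These functions wire together simulation, merging, mapping and damage
profiling under the standard double-strand library conditions (16.5 kb
circular mitogenome, lognormal fragment sizes, 2x100 paired reads) so
that estimator properties can be measured reproducibly.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

from . import simulate
from .assemble import map_reads, remove_duplicates
from .damage import MisincorporationTable, authenticate, profile_damage
from .merge import MergeParams, filter_merged, merge_pairs, read_fastq_pairs
from .simulate import DamageModel, FragmentationModel


@dataclass
class DamageEstimate:
    table: MisincorporationTable
    c2t_5p: float | None
    g2a_3p: float | None
    c2t_opportunities: int
    g2a_opportunities: int
    n_reads_profiled: int
    verdict_status: str


def _estimate_from_table(table: MisincorporationTable) -> DamageEstimate:
    return DamageEstimate(
        table=table,
        c2t_5p=table.frequency("5p", 1, "C>T"),
        g2a_3p=table.frequency("3p", 1, "G>A"),
        c2t_opportunities=int(table.counts[0, 0, 1, :].sum()),
        g2a_opportunities=int(table.counts[1, 0, 2, :].sum()),
        n_reads_profiled=table.n_reads,
        verdict_status=authenticate(table).status,
    )


def profile_true_placements(damage: DamageModel, n_fragments: int, seed: int,
                            mean_length: float = 60.0,
                            genome_length: int = 16500) -> DamageEstimate:
    """Simulate fragments and profile them at their true coordinates.

    Measures the damage generator + profiler pair with no mapping
    selection effect (reads are placed where they were simulated).
    """
    ref = simulate.simulate_reference(genome_length, 0.4, seed)
    frag = FragmentationModel(mean_length=mean_length)
    coords, seqs, _ = simulate.simulate_damaged_fragments(
        ref, frag, damage, seed + 1, n_fragments=n_fragments)
    records = simulate.true_alignments(ref, coords, seqs)
    table = profile_damage(records, ref.codes)
    return _estimate_from_table(table)


def simulate_merge_map_profile(damage: DamageModel, n_fragments: int, seed: int,
                               mean_length: float = 60.0,
                               genome_length: int = 16500,
                               read_length: int = 100) -> DamageEstimate:
    """Full path: simulate -> paired FASTQ -> merge -> map -> dedup -> profile.

    The damage profile is computed against the true reference, as when
    authenticating reads mapped to a known mitogenome.
    """
    ref = simulate.simulate_reference(genome_length, 0.4, seed)
    frag = FragmentationModel(mean_length=mean_length)
    coords, seqs, _ = simulate.simulate_damaged_fragments(
        ref, frag, damage, seed + 1, n_fragments=n_fragments)
    with tempfile.TemporaryDirectory() as tmp:
        r1, r2 = os.path.join(tmp, "r1.fastq"), os.path.join(tmp, "r2.fastq")
        simulate.emit_fastq_pairs(seqs, read_length, r1, r2, seed + 2)
        merged, _ = merge_pairs(read_fastq_pairs(r1, r2), MergeParams())
        merged, _ = filter_merged(merged, MergeParams())
    alignments = remove_duplicates(map_reads(merged, ref, damage_aware=True))
    table = profile_damage(alignments, ref.codes)
    return _estimate_from_table(table)
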