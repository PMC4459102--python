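"""End-to-end orchestration: simulate -> merge -> assemble -> authenticate.

A single run directory receives every stage's intermediates (FASTQ,
consensus FASTA, coverage/stats/misincorporation TSVs) plus a JSON
report mirroring the per-sample summary layout of an ancient-mtDNA
study: merged-read counts, unique mapped reads, unique average
coverage, average read length, terminal damage percentages,
authentication verdict and consensus completeness.  A single global
seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import simulate
from .assemble import ConsensusParams, iterate_assembly, map_reads, remove_duplicates
from .damage import authenticate, profile_damage
from .merge import MergeParams, merge_files
from .simulate import DamageModel, FragmentationModel, ReferenceGenome


@dataclass
class RunConfig:
    """All stage parameters; defaults are the workflow's canonical values."""

    seed: int = 1
    out_dir: str = "megalomito_run"
    # simulation
    genome_length: int = 16500
    gc: float = 0.4
    fragmentation: FragmentationModel = field(default_factory=FragmentationModel)
    damage: DamageModel | None = field(default_factory=DamageModel)
    n_fragments: int | None = None
    read_length: int = 100
    error_rate: float = 0.0
    # processing
    merge_params: MergeParams = field(default_factory=MergeParams)
    consensus_params: ConsensusParams = field(default_factory=ConsensusParams)
    damage_aware: bool = True
    auth_threshold: float = 0.20
    profile_k: int = 25


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.default_rng(
        (seed, zlib.crc32(stage.encode()))).integers(2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the machine-readable report.

    Any stage failure marks the stage failed in the report and skips
    later stages instead of raising.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "config": _config_dict(config),
        "stages": {},
    }
    path = lambda name: os.path.join(config.out_dir, name)

    try:
        ref = simulate.simulate_reference(config.genome_length, config.gc,
                                          _stage_seed(config.seed, "reference"))
        coords, seqs, truths = simulate.simulate_damaged_fragments(
            ref, config.fragmentation, config.damage,
            _stage_seed(config.seed, "fragments"), n_fragments=config.n_fragments)
        simulate.emit_fastq_pairs(seqs, config.read_length, path("r1.fastq"),
                                  path("r2.fastq"), _stage_seed(config.seed, "fastq"),
                                  error_rate=config.error_rate)
        simulate.write_ground_truth(path("truth.json"), seed=config.seed, ref=ref,
                                    coords=coords, truths=truths, damage=config.damage)
        with open(path("reference.fasta"), "w") as fh:
            fh.write(f">{ref.id}\n{ref.sequence}\n")
        report["stages"]["simulate"] = {"status": "ok", "n_fragments": len(coords)}
    except Exception as exc:  # noqa: BLE001
        report["stages"]["simulate"] = {"status": "failed", "error": str(exc)}
        return _finish(report, config)

    try:
        stats = merge_files(path("r1.fastq"), path("r2.fastq"),
                            path("merged.fastq"), config.merge_params)
        report["stages"]["merge"] = {"status": "ok", **{k: int(v) for k, v in stats.items()}}
    except Exception as exc:  # noqa: BLE001
        report["stages"]["merge"] = {"status": "failed", "error": str(exc)}
        return _finish(report, config)

    try:
        from .merge import MergedRead
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        with open(path("merged.fastq")) as fh:
            reads = [MergedRead(i.split()[0], s, q, 0)
                     for i, s, q in FastqGeneralIterator(fh)]
        result = iterate_assembly(reads, ref, config.consensus_params,
                                  damage_aware=config.damage_aware)
        with open(path("consensus.fasta"), "w") as fh:
            fh.write(f">consensus\n{result.consensus}\n")
        np.savetxt(path("coverage.tsv"),
                   np.column_stack([np.arange(1, len(result.coverage) + 1),
                                    result.coverage]),
                   fmt="%d", delimiter="\t", header="pos\tdepth", comments="")
        report["stages"]["assemble"] = {
            "status": "failed" if result.failed else "ok",
            "unique_mapped_reads": result.unique_fragments,
            "mapped_reads": result.mapped_fragments,
            "unique_average_coverage": round(result.mean_unique_coverage, 2),
            "average_read_length": round(result.mean_read_length, 2),
            "consensus_completeness_pct": round(100 * result.fraction_covered, 2),
            "iterations": result.iterations,
        }
        if result.failed:
            return _finish(report, config)
    except Exception as exc:  # noqa: BLE001
        report["stages"]["assemble"] = {"status": "failed", "error": str(exc)}
        return _finish(report, config)

    try:
        mapping_ref = ReferenceGenome(
            "consensus_for_profiling",
            "".join(c if c in "ACGT" else r for c, r in
                    zip(result.consensus, ref.sequence)),
            circular=True)
        alignments = remove_duplicates(
            map_reads(reads, mapping_ref, config.damage_aware))
        consensus_codes = result.consensus_codes
        table = profile_damage(alignments, consensus_codes, k=config.profile_k)
        table.to_dataframe().to_csv(path("misincorporation.tsv"), sep="\t", index=False)
        verdict = authenticate(table, config.auth_threshold)
        with open(path("verdict.json"), "w") as fh:
            json.dump(verdict.to_dict(), fh, indent=2)
        c2t = verdict.c2t_5prime_terminal
        g2a = verdict.g2a_3prime_terminal
        report["stages"]["damage"] = {
            "status": "ok",
            "c2t_5prime_pct": None if c2t is None else round(100 * c2t, 2),
            "g2a_3prime_pct": None if g2a is None else round(100 * g2a, 2),
            "verdict": verdict.status,
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["damage"] = {"status": "failed", "error": str(exc)}
    return _finish(report, config)


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    return {k: convert(v) for k, v in dataclasses.asdict(config).items()}


def _finish(report: dict, config: RunConfig) -> dict:
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
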