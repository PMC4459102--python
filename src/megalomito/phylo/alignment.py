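"""Multiple alignments: masking, column filtering and pairwise mismatches.

Column filtering follows the "complete deletion" convention: excluded
regions (e.g. the hypervariable D-loop), columns containing any gap or
missing character, and columns where any designated low-coverage taxon
falls below the coverage threshold are removed before likelihood or
parsimony computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .._seq import decode, encode


@dataclass
class MultipleAlignment:
    """Equal-length rows over {A,C,G,T,N,-} as an (ntaxa, nsites) code matrix."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise ValueError("one row per taxon required")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.ids.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return decode(self.row(taxon))

    def subset_columns(self, keep: np.ndarray) -> "MultipleAlignment":
        return MultipleAlignment(list(self.ids), self.matrix[:, keep])

    @classmethod
    def from_sequences(cls, pairs: Sequence[tuple[str, str]]) -> "MultipleAlignment":
        ids = [name for name, _ in pairs]
        rows = [encode(seq) for _, seq in pairs]
        if len({len(r) for r in rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        return cls(ids, np.vstack(rows))

    @classmethod
    def from_fasta(cls, path: str) -> "MultipleAlignment":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.matrix):
                fh.write(f">{name}\n{decode(row)}\n")


def mask_alignment(aln: MultipleAlignment,
                   exclude_regions: Sequence[tuple[int, int]] = (),
                   coverage_masks: Mapping[str, np.ndarray] | None = None,
                   min_coverage_ok: bool = True,
                   ) -> tuple[MultipleAlignment, int]:
    """Drop excluded-region, gapped/missing and low-coverage columns.

    ``exclude_regions`` are 0-based half-open column intervals;
    ``coverage_masks`` maps a taxon id to a boolean per-column array
    that is True where that taxon's assembly coverage met the
    threshold.  Returns (filtered alignment, retained column count).
    """
    n = aln.n_sites
    keep = np.ones(n, dtype=bool)
    for start, end in exclude_regions:
        if not (0 <= start <= end <= n):
            raise ValueError(f"interval ({start}, {end}) outside [0, {n}]")
        keep[start:end] = False
    keep &= ~(aln.matrix > 3).any(axis=0)       # any gap (5) or missing (4)
    if coverage_masks:
        for taxon, mask in coverage_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if len(mask) != n:
                raise ValueError(f"coverage mask for {taxon} has wrong length")
            if taxon not in aln.ids:
                raise ValueError(f"unknown taxon {taxon}")
            keep &= mask
    return aln.subset_columns(keep), int(keep.sum())


def count_mismatches(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Pairwise differences over a shared coordinate frame.

    Returns (mismatches, compared_sites, unresolved_sites): columns
    where both bases are unambiguous nucleotides are compared; columns
    with N or a gap on either side count as unresolved, never as
    mismatches.
    """
    a, b = encode(seq_a), encode(seq_b)
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    resolved = (a < 4) & (b < 4)
    mismatches = int(((a != b) & resolved).sum())
    return mismatches, int(resolved.sum()), int((~resolved).sum())
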