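"""Terminal misincorporation profiling and ancient-DNA authentication.

Post-mortem cytosine deamination concentrates in single-stranded
fragment ends, so authentic ancient libraries show elevated C->T at the
5' terminus and (under double-strand library preparation) G->A at the
3' terminus, decaying into the read.  The profiler tabulates all twelve
substitution types at the first K positions from each end, conditional
on the reference base (count(X->Y at p) / count(ref==X at p)); a
library is called authentic when both terminal frequencies reach the
20% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import BASES, revcomp_codes
from .assemble import AlignmentRecord

_SUBS = [(i, j) for i in range(4) for j in range(4) if i != j]


@dataclass
class MisincorporationTable:
    """Position-by-substitution counts at read termini.

    ``counts[e, p, x, y]``: end e (0 = 5', 1 = 3'), 1-based position
    p+1 from that end, reference base x, read base y.  Opportunities for
    X->Y at p are ``counts[e, p, x, :].sum()``.
    """

    counts: np.ndarray  # (2, K, 4, 4) int64
    n_reads: int

    @property
    def k(self) -> int:
        return self.counts.shape[1]

    def frequency(self, end: str, position: int, sub: str) -> float | None:
        """Conditional frequency of e.g. ``sub="C>T"`` at 1-based ``position``.

        Returns None when there are no opportunities (undefined, not 0).
        """
        e = {"5p": 0, "3p": 1}[end]
        x, y = BASES.index(sub[0]), BASES.index(sub[2])
        opportunities = self.counts[e, position - 1, x, :].sum()
        if opportunities == 0:
            return None
        return float(self.counts[e, position - 1, x, y] / opportunities)

    def profile(self, end: str, sub: str) -> list[float | None]:
        return [self.frequency(end, p, sub) for p in range(1, self.k + 1)]

    def to_dataframe(self):
        """Long-form table: end, position, sub_type, count, opportunities, frequency."""
        import pandas as pd

        rows = []
        for e, end in ((0, "5p"), (1, "3p")):
            for p in range(self.k):
                for x, y in _SUBS:
                    opp = int(self.counts[e, p, x, :].sum())
                    cnt = int(self.counts[e, p, x, y])
                    rows.append({
                        "end": end, "position": p + 1,
                        "sub_type": f"{BASES[x]}>{BASES[y]}",
                        "count": cnt, "opportunities": opp,
                        "frequency": cnt / opp if opp else np.nan,
                    })
        return pd.DataFrame(rows)


def profile_damage(alignments: Sequence[AlignmentRecord], consensus_codes: np.ndarray,
                   k: int = 25) -> MisincorporationTable:
    """Tabulate terminal substitutions of reads against their reference.

    ``consensus_codes`` is the sequence the alignments were produced
    against (may contain N; N positions contribute no opportunities).
    Positions are read-sense: 5' window from the read's 5' terminus, 3'
    window indexed from its 3' terminus.
    """
    L = len(consensus_codes)
    doubled = np.concatenate([consensus_codes, consensus_codes])
    counts = np.zeros((2, k, 4, 4), dtype=np.int64)
    for rec in alignments:
        ref_win = doubled[rec.ref_start : rec.ref_end]
        read = rec.codes
        if rec.strand == "-":
            ref_win = revcomp_codes(ref_win)
            read = revcomp_codes(read)
        m = len(read)
        w = min(k, m)
        for e, (r_ref, r_read) in enumerate(
            ((ref_win[:w], read[:w]), (ref_win[m - w :][::-1], read[m - w :][::-1]))
        ):
            ok = (r_ref < 4) & (r_read < 4)
            pos = np.flatnonzero(ok)
            np.add.at(counts[e], (pos, r_ref[pos].astype(np.int64),
                                  r_read[pos].astype(np.int64)), 1)
    return MisincorporationTable(counts=counts, n_reads=len(alignments))


@dataclass
class AuthenticationVerdict:
    c2t_5prime_terminal: float | None
    g2a_3prime_terminal: float | None
    threshold: float
    status: str  # "authentic" | "not_authentic" | "indeterminate"

    @property
    def authentic(self) -> bool:
        return self.status == "authentic"

    def to_dict(self) -> dict:
        return {
            "c2t_5prime_terminal": self.c2t_5prime_terminal,
            "g2a_3prime_terminal": self.g2a_3prime_terminal,
            "threshold": self.threshold,
            "status": self.status,
            "authentic": self.authentic,
        }


def authenticate(table: MisincorporationTable, threshold: float = 0.20
                 ) -> AuthenticationVerdict:
    """Authentic iff 5' C->T and 3' G->A position-1 frequencies both >= threshold."""
    c2t = table.frequency("5p", 1, "C>T")
    g2a = table.frequency("3p", 1, "G>A")
    if c2t is None or g2a is None:
        status = "indeterminate"
    elif c2t >= threshold and g2a >= threshold:
        status = "authentic"
    else:
        status = "not_authentic"
    return AuthenticationVerdict(c2t, g2a, threshold, status)
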