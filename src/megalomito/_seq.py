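"""Nucleotide encoding shared across modules.

Bases are encoded as small integers (A=0, C=1, G=2, T=3, N=4, gap=5) in
numpy int8 arrays; all hot loops work on these codes rather than strings.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN-"
A, C, G, T, N, GAP = range(6)

_ENC = np.full(256, N, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# complement of codes: A<->T, C<->G; N and gap map to themselves
_COMP = np.array([T, G, C, A, N, GAP], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into int8 codes (unknown chars -> N)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
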