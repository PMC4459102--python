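"""Synthetic inputs for every pipeline stage.

Generates circular reference genomes, aDNA-like fragment sets with
terminal cytosine deamination, paired-end FASTQ files with adapter
read-through, alignments evolved on known trees, and collagen isotope
tables — so the whole workflow is testable without any external data.

The deamination model follows the standard double-strand library
geometry: each fragment end carries a single-stranded overhang whose
length decays geometrically (position p from the terminus is
single-stranded with probability q^p).  Cytosines inside an overhang
deaminate at rate ``delta_ss`` and appear as C->T at the read 5' end;
under a double-strand protocol the complementary library strand turns
the opposite end's overhang damage into 3' G->A, and because only one
of the two strands carries the overhang at a given molecule end, the
observable terminal substitution frequency is capped at 50%.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import A, C, G, T, decode, encode, revcomp_codes

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class ReferenceGenome:
    """A (typically circular) reference genome with optional annotations.

    Annotations are ``(name, start, end)`` 0-based half-open intervals;
    intervals may wrap the circular origin before normalization.
    """

    id: str
    sequence: str
    circular: bool = True
    annotations: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet restricted to ACGT")
        n = len(self.sequence)
        for name, start, end in self.annotations:
            if not (0 <= start % n < n and 0 <= (end - 1) % n < n):
                raise ValueError(f"annotation {name} outside [0, {n})")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def fragment_codes(self, start: int, end: int, strand: str) -> np.ndarray:
        """Decode a (possibly origin-wrapping) fragment to read-sense codes."""
        n = len(self.sequence)
        if end <= start:
            raise ValueError("end must exceed start")
        if not self.circular and end > n:
            raise ValueError("fragment beyond linear reference end")
        length = end - start
        if length > n:
            raise ValueError("fragment longer than the genome")
        start %= n
        codes = encode((self.sequence + self.sequence)[start : start + length])
        if strand == "-":
            codes = revcomp_codes(codes)
        return codes


@dataclass
class FragmentationModel:
    """Fragment-size model: lognormal lengths around ``mean_length``."""

    mean_length: float = 60.0
    dispersion: float = 0.35
    min_length: int = 30
    coverage_target: float = 30.0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length >= 1 required")
        if self.mean_length < self.min_length:
            raise ValueError("mean_length must be >= min_length")


@dataclass
class DamageModel:
    """Overhang-restricted deamination parameters.

    overhang_decay
        q in [0, 1]; position p (1-based) from a fragment end is
        single-stranded with probability q**p.  q=1 is the degenerate
        whole-fragment overhang.
    delta_ss
        C->U rate inside single-stranded overhangs.
    delta_ds
        residual double-stranded deamination rate (genome-wide).
    both_strands
        double-strand library protocol: each end's overhang sits on the
        sequenced strand with probability 1/2, and 3'-end overhang
        damage is observed as G->A.  With ``both_strands=False``
        (single-strand protocol analogue) every overhang is read
        directly, as C->T at both ends.
    """

    overhang_decay: float = 0.5
    delta_ss: float = 0.5
    delta_ds: float = 0.0
    both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("overhang_decay", "delta_ss", "delta_ds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def for_terminal_rate(cls, rate: float, delta_ds: float = 0.0) -> "DamageModel":
        """Double-strand model whose expected position-1 5' C->T frequency is ``rate``.

        With delta_ss fixed at 1 the position-1 expectation is q/2, so
        q = 2*rate; rate must therefore not exceed the 0.5 protocol cap.
        """
        if not 0.0 <= rate <= 0.5:
            raise ValueError("terminal rate exceeds the 50% double-strand cap")
        return cls(overhang_decay=2.0 * rate, delta_ss=1.0,
                   delta_ds=delta_ds, both_strands=True)

    def expected_ct_frequency(self, position: int) -> float:
        """Closed-form P(read T | template C) at 1-based distance ``position`` from the 5' end."""
        q, dss, dds = self.overhang_decay, self.delta_ss, self.delta_ds
        p_ss = (0.5 if self.both_strands else 1.0) * q**position
        p_deam = p_ss * (dss + (1 - dss) * dds) + (1 - p_ss) * dds
        return p_deam


def simulate_reference(length: int, gc: float, seed: int,
                       annotations: Sequence[tuple[str, int, int]] = (),
                       id: str = "synthetic_mt") -> ReferenceGenome:
    """Random circular genome of exactly ``length`` bases at GC fraction ``gc``."""
    if length < 100:
        raise ValueError("length >= 100 required")
    if not 0.0 <= gc < 1.0:
        raise ValueError("gc must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.array([A, C, G, T], dtype=np.int8), size=length, p=probs)
    return ReferenceGenome(id=id, sequence=decode(codes), circular=True,
                           annotations=list(annotations))


def simulate_fragments(ref: ReferenceGenome, frag: FragmentationModel,
                       seed: int, n_fragments: int | None = None
                       ) -> list[tuple[int, int, str]]:
    """Draw fragments (start, end, strand) to the model's coverage target.

    ``end`` may exceed the genome length for origin-wrapping fragments;
    coordinates are unwrapped 0-based half-open.
    """
    if n_fragments is None:
        if frag.coverage_target <= 0:
            raise ValueError("coverage_target > 0 required")
        n_fragments = max(1, round(frag.coverage_target * len(ref) / frag.mean_length))
    rng = np.random.default_rng(seed)
    sigma = frag.dispersion
    mu = math.log(frag.mean_length) - sigma**2 / 2
    lengths = np.maximum(
        np.round(rng.lognormal(mu, sigma, size=n_fragments)).astype(int),
        frag.min_length,
    )
    starts = rng.integers(0, len(ref), size=n_fragments)
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    return [(int(s), int(s + l), str(st)) for s, l, st in zip(starts, lengths, strands)]


def apply_damage(codes: np.ndarray, model: DamageModel,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Deaminate one fragment (read-sense codes); returns (damaged, ground truth).

    Ground truth is a list of ``(position, "C>T" | "G>A")`` in read
    coordinates.  Only C->T (and, under the double-strand protocol,
    3'-originating G->A) changes are ever introduced.
    """
    n = len(codes)
    if n == 0:
        raise ValueError("fragment must be non-empty")
    out = codes.copy()
    truth: list[tuple[int, str]] = []
    q = model.overhang_decay

    def overhang_len() -> int:
        if q >= 1.0:
            return n
        if q <= 0.0:
            return 0
        # P(L >= p) = q^p  <=>  L = Geometric(1-q) - 1
        return min(int(rng.geometric(1.0 - q)) - 1, n)

    def hit(positions: np.ndarray, base: int, rate: float, label: str) -> None:
        cand = positions[out[positions] == base]
        if len(cand) == 0 or rate <= 0.0:
            return
        chosen = cand[rng.random(len(cand)) < rate]
        out[chosen] = T if base == C else A
        truth.extend((int(p), label) for p in chosen)

    # 5' overhang: C->T on the read sense (coin-flip for which library
    # strand carries the overhang under the double-strand protocol)
    if not model.both_strands or rng.random() < 0.5:
        l5 = overhang_len()
        if l5:
            hit(np.arange(l5), C, model.delta_ss, "C>T")
    # 3' overhang: G->A under double-strand (complement fill-in), C->T otherwise
    if model.both_strands:
        if rng.random() < 0.5:
            l3 = overhang_len()
            if l3:
                hit(np.arange(n - l3, n), G, model.delta_ss, "G>A")
    else:
        l3 = overhang_len()
        if l3:
            hit(np.arange(n - l3, n), C, model.delta_ss, "C>T")
    # residual double-stranded deamination anywhere
    if model.delta_ds > 0:
        everywhere = np.arange(n)
        hit(everywhere, C, model.delta_ds, "C>T")
        if model.both_strands:
            hit(everywhere, G, model.delta_ds, "G>A")
    return out, sorted(truth)


def simulate_damaged_fragments(ref: ReferenceGenome, frag: FragmentationModel,
                               damage: DamageModel | None, seed: int,
                               n_fragments: int | None = None):
    """Convenience: fragments + damaged read-sense sequences + ground truth.

    Returns ``(coords, seq_codes, truths)`` with one entry per fragment.
    """
    coords = simulate_fragments(ref, frag, seed, n_fragments=n_fragments)
    rng = np.random.default_rng((seed, 0xDA1A))
    seqs, truths = [], []
    for start, end, strand in coords:
        codes = ref.fragment_codes(start, end, strand)
        if damage is not None:
            codes, truth = apply_damage(codes, damage, rng)
        else:
            truth = []
        seqs.append(codes)
        truths.append(truth)
    return coords, seqs, truths


def emit_fastq_pairs(fragments: Sequence[np.ndarray], read_length: int,
                     out_r1: str, out_r2: str, seed: int,
                     adapter: str = DEFAULT_ADAPTER, error_rate: float = 0.0,
                     quality_char: str = "F", ids: Sequence[str] | None = None) -> int:
    """Write paired FASTQ (Phred+33) from read-sense fragment codes.

    Mate 1 reads the fragment 5'->3'; mate 2 reads the reverse
    complement; fragments shorter than ``read_length`` read through into
    the adapter.  Returns the number of pairs written.
    """
    if read_length <= 0:
        raise ValueError("read_length > 0 required")
    rng = np.random.default_rng((seed, 0xFA57))
    adapter_codes = encode(adapter * (read_length // len(adapter) + 2))
    qual = quality_char * read_length

    def make_read(codes: np.ndarray) -> str:
        if len(codes) >= read_length:
            read = codes[:read_length].copy()
        else:
            read = np.concatenate([codes, adapter_codes[: read_length - len(codes)]])
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if len(errs):
                read[errs] = (read[errs] + rng.integers(1, 4, size=len(errs))) % 4
        return decode(read)

    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for i, codes in enumerate(fragments):
            rid = ids[i] if ids is not None else f"frag{i}"
            f1.write(f"@{rid}\n{make_read(codes)}\n+\n{qual}\n")
            f2.write(f"@{rid}\n{make_read(revcomp_codes(codes))}\n+\n{qual}\n")
    return len(fragments)


def write_ground_truth(path: str, *, seed: int, ref: ReferenceGenome,
                       coords, truths, damage: DamageModel | None) -> None:
    """JSON sidecar recording the simulation's full ground truth."""
    payload = {
        "seed": seed,
        "reference_id": ref.id,
        "reference_length": len(ref),
        "damage_model": dataclasses.asdict(damage) if damage else None,
        "fragments": [
            {"start": s, "end": e, "strand": st, "damage": tr}
            for (s, e, st), tr in zip(coords, truths)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def true_alignments(ref: ReferenceGenome, coords, seqs, quality: int = 37):
    """AlignmentRecords at the simulated ground-truth coordinates.

    Bypasses the mapper, so estimator properties can be measured free of
    any mapping selection effect.
    """
    from .assemble import AlignmentRecord

    n = len(ref)
    records = []
    for i, ((start, end, strand), codes) in enumerate(zip(coords, seqs)):
        ref_sense = codes if strand == "+" else revcomp_codes(codes)
        records.append(AlignmentRecord(
            f"frag{i}", start % n, start % n + (end - start), strand,
            f"{end - start}M", float(end - start), ref_sense,
            np.full(end - start, quality, dtype=np.int16)))
    return records


# ---------------------------------------------------------------------------
# sequence evolution on a tree (test harness for the phylogenetics stage)

def simulate_alignment_on_tree(tree, model, n_sites: int, seed: int):
    """Evolve i.i.d. sites under GTR+G+I down ``tree`` (root at stationarity).

    ``tree`` is a :class:`megalomito.phylo.tree.Node`; ``model`` a
    :class:`megalomito.phylo.model.PhyloModel`.  Returns a
    :class:`megalomito.phylo.alignment.MultipleAlignment`.
    """
    from .phylo.alignment import MultipleAlignment

    for node in tree.postorder():
        if node.children and len(node.children) not in (2, 3):
            raise ValueError("tree must be binary (trifurcating root allowed)")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()          # includes the invariant category
    probs = model.category_probs()
    site_cat = rng.choice(len(rates), size=n_sites, p=probs)
    site_rate = rates[site_cat]
    states = {id(tree): rng.choice(4, size=n_sites, p=model.frequencies)}
    rows, ids = [], []
    for node in tree.preorder():
        if node is not tree:
            parent_states = states[id(node.parent)]
            child = parent_states.copy()
            for k, r in enumerate(np.unique(site_rate)):
                mask = site_rate == r
                P = model.transition_matrix(node.length * r)
                cum = P.cumsum(axis=1)
                u = rng.random(mask.sum())
                child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
            states[id(node)] = child
        if not node.children:
            ids.append(node.name)
            rows.append(states[id(node)].astype(np.int8))
    return MultipleAlignment(ids, np.vstack(rows))


# ---------------------------------------------------------------------------
# collagen isotope tables

@dataclass
class IsotopeGroup:
    taxon: str
    period: str                 # "pre-LGM" | "late-glacial"
    mean_d13c: float            # permil vs V-PDB
    mean_d15n: float            # permil vs AIR
    sd_d13c: float
    sd_d15n: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n >= 1 per group")
        if self.sd_d13c < 0 or self.sd_d15n < 0:
            raise ValueError("group sds must be >= 0")


@dataclass
class IsotopeSimSpec:
    """Cluster layout plus instrument noise for simulated collagen tables."""

    groups: list[IsotopeGroup]
    noise_d13c: float = 0.1     # analytic error, permil
    noise_d15n: float = 0.2
    cn_valid_range: tuple[float, float] = (2.9, 3.6)
    invalid_cn_fraction: float = 0.0


def default_isotope_spec(invalid_cn_fraction: float = 0.0) -> IsotopeSimSpec:
    """Cervid clusters: distinct pre-LGM niches, converged late-glacial ones.

    Pre-LGM reindeer sit ~2 permil higher in d13C than red deer and
    giant deer (lichen feeding); after the LGM the three species'
    signatures converge onto a common cluster.
    """
    groups = [
        IsotopeGroup("Rangifer", "pre-LGM", -18.3, 2.9, 0.4, 0.8, 12),
        IsotopeGroup("Cervus", "pre-LGM", -20.6, 4.8, 0.5, 0.9, 12),
        IsotopeGroup("Megaloceros", "pre-LGM", -20.3, 4.9, 0.4, 0.8, 8),
        IsotopeGroup("Rangifer", "late-glacial", -19.4, 3.2, 0.5, 0.9, 12),
        IsotopeGroup("Cervus", "late-glacial", -20.0, 3.6, 0.5, 0.9, 12),
        IsotopeGroup("Megaloceros", "late-glacial", -19.8, 3.4, 0.3, 0.7, 4),
    ]
    return IsotopeSimSpec(groups=groups, invalid_cn_fraction=invalid_cn_fraction)


def simulate_isotope_table(spec: IsotopeSimSpec, seed: int):
    """Simulated collagen table as a pandas DataFrame.

    Columns: sample, taxon, period, d13C, d15N, pctC, pctN.  A fraction
    ``invalid_cn_fraction`` of records receives a C/N atomic ratio
    outside the validity window to exercise downstream QC.
    """
    import pandas as pd

    if not spec.groups:
        raise ValueError("at least one group required")
    rng = np.random.default_rng(seed)
    rows = []
    lo, hi = spec.cn_valid_range
    for g in spec.groups:
        for i in range(g.n):
            d13c = rng.normal(g.mean_d13c, g.sd_d13c) + rng.normal(0, spec.noise_d13c)
            d15n = rng.normal(g.mean_d15n, g.sd_d15n) + rng.normal(0, spec.noise_d15n)
            if rng.random() < spec.invalid_cn_fraction:
                cn = rng.uniform(3.8, 4.6) if rng.random() < 0.5 else rng.uniform(2.0, 2.7)
            else:
                cn = rng.uniform(lo + 0.05, hi - 0.05)
            pct_c = rng.uniform(35.0, 45.0)           # wt% C of good collagen
            pct_n = pct_c * 14.007 / (12.011 * cn)    # back-solve N wt% from target C/N
            rows.append({
                "sample": f"{g.taxon[:4]}_{g.period[:3]}_{i:03d}",
                "taxon": g.taxon, "period": g.period,
                "d13C": round(d13c, 2), "d15N": round(d15n, 2),
                "pctC": round(pct_c, 2), "pctN": round(pct_n, 3),
            })
    return pd.DataFrame(rows)
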