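# Methods

This note documents the models behind `megalomito`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
data can and cannot establish about real ancient-DNA workflows.

## Deamination model

A recovered double-stranded DNA fragment is modelled with an
independent single-stranded overhang at each end. Overhang length
follows a geometric law parameterized by a decay constant `q`
(`overhang_decay`): position `p` (1-based from the fragment end) is
single-stranded with probability `q^p`. Cytosines inside an overhang
deaminate (C→U, read as T) with probability `delta_ss`; a residual
genome-wide rate `delta_ds` covers double-stranded deamination.

Under a double-strand library protocol (`both_strands=True`) both
strands of every molecule enter the library, but the overhang at a given
molecule end sits on only one of them. We model this as a fair coin per
fragment end: with probability 1/2 the sequenced strand carries the
5′-overhang damage (read as 5′ C→T) and with probability 1/2 the 3′-end
overhang of the complementary strand is read through end repair as
3′ G→A. Two exact consequences, both verified by the test suite:

- the expected position-1 frequency is `0.5 · q · delta_ss` (plus a
  `delta_ds` term), so observable terminal damage is capped at **50%**
  even at complete overhang deamination — the signature ceiling of
  double-strand libraries;
- the 5′ C→T and 3′ G→A profiles are equal in expectation at every
  position (strand symmetry).

With `both_strands=False` (single-strand protocol analogue) every
overhang is read directly and deamination appears as C→T at both ends,
reaching 100% at saturation.

`DamageModel.for_terminal_rate(f)` inverts the closed form with
`delta_ss = 1`, `q = 2f`: convenient for simulating a library whose
terminal rate is a target value such as 27% or 49%. `q = 1` is allowed
as the degenerate whole-fragment overhang, needed to realize the 50%
ceiling exactly.

Limitations: real overhang-length distributions need not be geometric;
nicks, depurination-driven fragmentation bias, base-composition bias at
fragment ends, and quality-score correlation with damage are not
modelled. Consequently passing tests demonstrate estimator correctness
under the stated generative model, not robustness to every property of
real libraries.

## Fragment sizes and read geometry

Published mean fragment lengths for well-preserved Pleistocene bone
fall around 60–85 bp; only means being available, the length
distribution family is a free choice and we use a lognormal
(σ = 0.35) truncated below at 30 bp, a realistic right-skewed shape for
aDNA. Reads are 2×100 with constant Q37 qualities (no quality model is
specified by any source we emulate) and uniform sequencing errors when
requested; fragments shorter than the read length read through into the
adapter.

## Merging

Mate 1 is scanned against the reverse complement of mate 2 over all
overlap offsets (seeded by exact 16-mers for speed, with an exhaustive
fallback; an oracle test checks equivalence). Scoring is matches −
mismatches within the overlap, ties broken toward the longer overlap;
an overlap is accepted at ≥ 11 bp and mismatch fraction ≤ 0.1 (the 11 bp
minimum is the protocol constant; the mismatch tolerance is our default,
chosen to tolerate damage-induced disagreement, and is not a published
value). In the overlap the higher-quality base and its quality are kept
(ties favor mate 1); N matches nothing. When the mates overhang each
other (fragment shorter than the reads) the merged read is restricted to
the overlap, which removes adapters without an explicit trimming step.
Unmerged pairs are discarded; merged reads under 30 bp are filtered.

## Mapping and iterative assembly

Reads are placed on the doubled (circular) reference by gapless
diagonal scoring: candidate diagonals come from two k-mer indexes — an
exact 16-mer index and a purine/pyrimidine-collapsed 24-mer index, the
latter insensitive to C→T/G→A changes so that heavily deaminated reads
still seed. References at or below 2 kb are scored at every diagonal.
Match +1, mismatch −1; with damage-aware scoring the penalty of a C→T
(G→A) mismatch is multiplied by `q_map^p` with `p` the distance from the
5′ (3′) read terminus and `q_map = 0.5`, so deamination-consistent
mismatches near an end are cheap and even interior ones are only mildly
penalized, while the other ten substitution types pay full price. Reads
scoring below half their length are unmapped — random (contaminant)
sequence scores near zero against a 16.5 kb reference, so the threshold
separates the two populations by a wide margin.

The scorer is gapless by design: the substitution-only generative
model, and reference divergence modelled as substitutions, leave no
code path that would exercise indel alignment; records carry all-match
edit strings. Indel-aware banded alignment is the natural extension
point if structurally divergent references are ever needed.

Duplicates are defined by identical (start, end, strand) — both
endpoints, matching "unique mapped fragments" semantics — and collapsed
to the copy with the highest summed base quality. The consensus emits
the majority base where unique coverage ≥ 3 and the majority fraction
≥ 0.5 with a unique maximum; ties and sub-threshold positions are N.
Iteration replaces N with the previous mapping base for mapping purposes
only, stops on a byte-identical consensus, and caps at 10 rounds.
Internally coordinates are 0-based half-open; reports are 1-based.

## Damage profiling and authentication

Misincorporation frequencies are conditional on the reference base
(count(X→Y at p) / count(ref = X at p), the mapDamage convention) for
all twelve substitution types at the first K = 25 positions from each
read end, 3′ positions indexed from the read's 3′ terminus. The
conditional definition is the one under which the 50% double-strand
ceiling is exact. Positions whose reference base is N contribute no
opportunities; a position with zero opportunities reports a missing
frequency, never 0. A library is authentic iff both the 5′ C→T and
3′ G→A position-1 frequencies are ≥ 0.20 (inclusive); an undefined
terminal frequency yields an "indeterminate" verdict.

One measured subtlety: estimating frequencies from *mapped* reads
conditions on mappability. At moderate damage (≤ 30%) the effect is
unmeasurable; at 49% terminal damage about 0.2% of reads (those with
long overhangs at both ends) fall below the mapping threshold and the
estimate shifts by roughly −0.5 percentage points — within the
estimator's 2 SE at the simulation sizes used. Estimator-consistency
tests therefore run either against ground-truth placements (no
conditioning) or through the full mapping path, as appropriate to the
claim being tested.

## Phylogenetics

- **Masking**: complete deletion — excluded regions (e.g. the D-loop),
  any column containing a gap or N, and any column where a designated
  ancient taxon's assembly coverage is below threshold are removed
  before analysis.
- **Model**: GTR parameterized by six exchangeabilities and stationary
  frequencies, normalized to unit mean rate; transition matrices via
  symmetrized eigendecomposition (rows renormalized against roundoff).
  Rate heterogeneity: discrete gamma with 5 equal-probability
  categories, category rate = mean of its quantile bin, default shape
  α = 0.3366; an invariant-sites proportion rescales the variable
  categories by 1/(1−p_inv) so the overall mean rate is exactly 1.
- **Likelihood**: Felsenstein pruning over unique site patterns
  (cached per alignment); N/gap are missing data (unit partials); the
  invariant category contributes Σ_x π_x for sites compatible with
  constancy. Verified against the two-taxon Jukes–Cantor closed form,
  brute-force summation over internal states, and the pulley principle
  (root-placement invariance).
- **Parsimony**: Fitch bitmask dynamic program; trees with a
  trifurcating root are first rooted on an edge (score-preserving).
  Per-branch step counts come from one most-parsimonious traceback with
  ties resolved toward the alphabetically first base; branch steps sum
  to the total score.
- **Search**: NJ start tree (log-det distances for ML, p-distances for
  MP; negative NJ branch lengths clamped to 0), then first-improvement
  NNI hill climbing. ML branch lengths are optimized per-branch by
  bounded Brent (tolerance 1e-6), cycled until the log-likelihood gains
  < 1e-4; candidate NNI neighbors are ranked after a single optimization
  cycle and re-optimized fully on acceptance. Taxa are sorted before the
  distance matrix so results are input-order invariant; all stochastic
  steps take an explicit seed.
- **Bootstrap**: column resampling with replacement, full re-search per
  replicate, support = percentage of replicates containing each
  bipartition of the point tree (bipartitions anchored to the
  lexicographically smallest taxon for rooting-independent comparison).
- **Mismatch counting**: pairwise differences over a shared coordinate
  frame count only columns where both bases are unambiguous; N or gap
  columns are reported as unresolved so that partially reconstructed
  sequences are never charged differences for missing data.

The published tree for the motivating study compares against ~44
external mitogenomes and is not reproducible offline; correctness here
rests on exhaustive oracles at 4–6 taxa and topology recovery on data
simulated from known 8-taxon trees, which the test suite runs at
2,500–10,000 sites (sizes chosen to give unambiguous signal at
second-scale runtimes).

## Isotopes

The atomic C/N ratio is always derived from weight percentages,
(pctC/12.011)/(pctN/14.007), never accepted from input; records are
retained iff 2.9 ≤ C/N ≤ 3.6 (inclusive, "within the range"), with
missing composition flagged unassessable. Group summaries report
mean/sd/n per taxon-period; sd is missing below n = 2. Niche overlap is
area(intersection)/area(union) of the two groups' convex hulls in the
(δ¹³C, δ¹⁵N) plane — an analytic operationalization of the visual
"falls inside the cluster" argument, not a published formula — with
collinear groups falling back to segment-length overlap and flagged
degenerate. The default simulated clusters place pre-LGM reindeer
~2‰ higher in δ¹³C than red deer and giant deer (lichen diet) and
converge all three after the LGM, so the directional claim — overlap
increases post-LGM — is testable; analytic noise is 0.1‰ (δ¹³C) and
0.2‰ (δ¹⁵N).

## Pipeline and reproducibility

`run_pipeline` fans a single global seed out to per-stage seeds via
CRC-stable hashing, serializes the full configuration into the report,
and persists every intermediate (FASTQ, merged reads, consensus,
coverage track, misincorporation table, verdict) so each reported
number is recomputable from files on disk. A stage failure marks the
report and skips downstream stages rather than raising.

The acceptance script simulates 100,000 fragments per condition — large
enough that binomial error on a terminal frequency is ~0.2–0.3
percentage points, small enough for single-CPU minutes — and reports
terminal-substitution percentages recovered through the same code path
the pipeline uses.
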