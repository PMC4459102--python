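# megalomito

Reconstruction and authentication of ancient mitochondrial genomes,
with phylogenetic placement and collagen stable-isotope niche analysis.

Ancient bone rarely yields intact DNA: what survives are short
(~30–100 bp) fragments whose single-stranded ends accumulate cytosine
deamination, read out as C→T substitutions at the 5′ terminus and — under
double-strand library preparation — G→A at the 3′ terminus. This package
implements the complete desk-side workflow for such data:

1. **Simulation** (`megalomito.simulate`) — circular reference genomes,
   lognormal fragment sizes, Briggs-style overhang deamination with a
   geometric length law (position *p* from a fragment end is
   single-stranded with probability *q^p*), paired-end FASTQ with adapter
   read-through, sequence evolution on trees, and collagen isotope tables.
   Every simulation records its ground truth.
2. **Read processing** (`megalomito.merge`) — mates overlapping by ≥ 11 bp
   are merged (higher-quality base wins in the overlap; read-through
   geometry trims adapters implicitly); merged reads shorter than 30 bp
   are discarded.
3. **Iterative assembly** (`megalomito.assemble`) — reads are placed on
   the circular reference by seeded, gapless, damage-aware alignment
   (terminal C→T/G→A mismatch penalties are discounted by *q^p*),
   duplicates sharing both mapping coordinates and strand are collapsed,
   and a majority consensus is called wherever unique coverage is ≥ 3-fold
   (N elsewhere). The consensus replaces the reference and mapping repeats
   until the consensus is stable, so a congeneric starting reference
   converges onto the sample's own sequence.
4. **Damage authentication** (`megalomito.damage`) — positional
   misincorporation frequencies, conditional on the reference base, at the
   first 25 positions from each read end. A library is *authentic* when
   both the 5′ C→T and 3′ G→A position-1 frequencies reach 20%. The
   theoretical ceiling under a double-strand protocol is 50%.
5. **Phylogenetics** (`megalomito.phylo`) — alignment masking (excluded
   regions such as the hypervariable D-loop, gap/missing columns,
   low-coverage columns), GTR+G+I log-likelihood by Felsenstein pruning
   (5 gamma categories, mean-of-quantile discretization, default shape
   α = 0.3366), Fitch parsimony with per-branch step counts,
   NJ + NNI tree search under either criterion, bootstrap supports,
   outgroup rooting, and pairwise mismatch counting for marker genes
   (unresolved bases count as uncompared, never as differences).
6. **Isotopes** (`megalomito.isotopes`) — collagen quality control by the
   atomic C/N ratio (retained iff 2.9 ≤ C/N ≤ 3.6) and niche comparison as
   convex-hull overlap in the (δ¹³C, δ¹⁵N) plane, with inside/outside
   classification of query specimens.

## Worked example

```bash
megalomito run-all --seed 5 --out-dir run --coverage 15 --terminal-ct 0.27
```

simulates a 16.5 kb circular mitogenome at 15× coverage with a 27%
expected terminal C→T rate, merges, assembles and authenticates, and
writes `run/report.json`. With a 3 kb genome (the configuration used in
the test suite) the report reads:

```json
"merge":    {"status": "ok", "total_pairs": 750, "merged": 750,
             "discarded_unmerged": 0, "discarded_short": 0, "retained": 750},
"assemble": {"status": "ok", "unique_mapped_reads": 749, "mapped_reads": 750,
             "unique_average_coverage": 14.82, "average_read_length": 59.37,
             "consensus_completeness_pct": 100.0, "iterations": 2},
"damage":   {"status": "ok", "c2t_5prime_pct": 30.77, "g2a_3prime_pct": 32.82,
             "verdict": "authentic"}
```

Reading it: all 750 simulated pairs merged; after duplicate removal 749
unique fragments give ≈15× unique coverage and a complete ≥3-fold
consensus; the observed terminal substitution frequencies (30.8% /
32.8%, scattered around the 27% generative expectation at this modest
read count) both clear the 20% rule, so the library is called authentic
ancient DNA. A blank (undamaged) library run the same way reports 0% at
both termini and `"not_authentic"`.

Each stage is also available separately (`megalomito simulate | merge |
assemble | damage | phylo | isotopes`); see `--help`.

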