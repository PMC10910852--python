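# Methods

## Scope and model

spacernet analyses collections of CRISPR arrays at the spacer level. The
underlying biological model is the Type I-E CRISPR1 locus of *E. coli*: an
array of n spacers (canonically 32 nt) interleaved with n+1 copies of a
conserved 29-nt direct repeat, acquired 5'-polarised at the leader end. A
spacer's target (protospacer) is any full-length, gapless occurrence of
the spacer in another sequence within a small substitution budget; targets
concentrated in one chromosomal neighbourhood indicate an integrated
prophage rather than chromosome-wide self-targeting.

## Pipeline stages and the parameters that matter

| stage | parameter | default | units | rationale |
|---|---|---|---|---|
| extraction | repeat mismatch tolerance | 3 | substitutions | terminal repeats are often degenerate; gapless keeps the scan exact |
| extraction | spacer length bounds | 20–50 | nt | brackets the canonical 32 nt; rejects long insertions (e.g. the ~0.5-kb AT-rich element that splits some arrays) |
| search | max mismatches | 4 | substitutions | standard interference-tolerant cut-off for a 32-nt spacer, full length, zero gaps |
| masking | repeat-proximity window | 100 | bp (interval gap; overlap = 0) | spacers inside arrays must not count as targets |
| network | null replicates / percentile | 500 / 95th | — | pooled nearest-rank percentile over all sharing pairs and replicates |
| prophage | min hits / flank | 10 / 25 000 | hits / bp | subjects with ≥10 clustered targets get one min–max span ± flank |
| dedup | identity / coverage | 95 / 85 | % | species-level viral deduplication; coverage relative to the shorter sequence |
| MCL | inflation / tol / max_iter | 2.0 / 1e-6 / 100 | — | standard granularity; tol doubles as pruning threshold and convergence test |
| selftarget | match stringency | 0 | mismatches | "present elsewhere" read as exact; the 4-mismatch rule is available by flag |

## Algorithmic choices

**Protospacer matcher.** The query is split into `max_mismatches + 1`
contiguous segments; any window within tolerance must contain at least one
segment exactly (pigeonhole), so exact segment occurrences enumerate all
candidates, which are verified by direct Hamming count. Both strands are
searched; minus-strand hits are reported in forward coordinates. Ambiguity
codes in subjects count as mismatches (conservative on low-quality
contigs). A brute-force vectorised scan over every window is kept as an
independent oracle in the tests; the two must agree exactly.

**Permutation null.** One replicate permutes the pooled spacer multiset
and repartitions it by the original per-isolate counts, so per-isolate
counts and the global multiset are conserved exactly; within-isolate
duplicates may occur. Null values are pooled across all pairs and
replicates before taking a single nearest-rank percentile — one global
threshold, no per-pair calibration, no interpolation ambiguity. Edges
exactly at the threshold are kept (removal applies strictly below it).

**Module detection** is pluggable (connected components, asynchronous
label propagation, greedy modularity). Greedy modularity is the default:
deterministic, dependency-free, and on planted-pool cohorts it recovers
the latent partition with adjusted Rand ≥ 0.97 across seeds. Map-equation
optimisers are deliberately not re-implemented; any external partitioner
can be applied to the exported graph.

**MAD and region calling.** MAD is unscaled (no 1.4826 consistency
factor): it is a dispersion proxy for "are the targets in one place", not
a standard-deviation estimator. It is reported only for subjects with ≥ 2
hits. Region calling uses min hit start / max hit end ± flank, clipped to
the sequence; one region per subject, so multi-prophage genomes yield a
single merged span — a documented limitation of the min–max procedure.

**Pairwise identity** is a gapless anchored alignment: shared k-mers
(k = 15, either strand) propose diagonals, the best diagonal (most
matching columns, evaluated over the full overlap) is scored as
identity = matches/aligned columns and coverage = aligned columns/shorter
length. Divergence in the data this is designed for is substitution-only,
so one diagonal suffices; an exhaustive all-diagonal oracle backs it in
tests. Coverage relative to the shorter sequence treats containment as
full coverage (the containment-friendly reading; relative-to-longer is
the noted alternative).

**MCL** follows the canonical iteration on the column-stochastic matrix
with unit self-loops: expansion (squaring), inflation (elementwise power,
column renormalisation), pruning of entries below `tol`, until the matrix
changes by less than `tol`. Clusters are read as connected components of
the converged non-zero structure, which provably never merges components
of the input graph. Representatives are the longest member, ties broken
lexicographically.

**Lifestyle flag** is a keyword heuristic over product annotations
(integrase, serine/tyrosine recombinase, excisionase, CI repressor,
lysogeny, antirepressor); its output is labelled heuristic and is not a
substitute for genome-based lifecycle prediction.

**Self-targeting.** Array intervals are repeat occurrences extended by
100 bp and merged, so any target outside them is automatically > 100 bp
from every repeat. The plasmid exception is applied record-wise: a spacer
resident in an array whose only extra copies are on plasmid records is
excluded from events but reported in a separate ledger.

**Coordinates.** Public dataclasses and all TSV outputs are 1-based
inclusive on the forward strand (declared in a header comment); BED
exports are 0-based half-open; algorithms index 0-based internally.

## Synthetic data: what it emulates, what it does not

The generator emulates the study design the pipeline is meant for:
isolates grouped into latent modules drawing spacers from module-specific
pools; pools sampled from synthetic prophage sequences with a controlled
per-spacer substitution count (never indels, matching the zero-gap rule);
decoy spacers with no origin; genomes with implanted prophages and
repeat–spacer–repeat arrays at recorded coordinates; optional plasmid
records. Implants use replacement semantics by default so coordinates of
other features stay stable; insertion is available by flag. Truth is
serialised as JSON next to the FASTA output, and identical seeds give
byte-identical files.

Default condition sizes: 32-nt spacers, 2–32 spacers per isolate, 40-kb
prophages, mismatch profile concentrated at 0–1 substitutions. Synthetic
backbones are i.i.d. uniform nucleotides: there is no repetitive DNA, no
IS elements, no compositional skew, and prophage content is random
sequence rather than phage genes. Passing tests therefore demonstrate
algorithmic correctness against known truth — exact matcher semantics,
conservation laws, recovery of planted structure — not robustness to
repeat-rich real genomes, where near-duplicate regions can produce extra
protospacer hits and merged regions.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run cohorts of 50–120 isolates
(5–12 modules), 60–100 genomes of 300 kb with one 40-kb prophage each,
500-replicate nulls, and 300–1000 random matcher/oracle pairs with
subjects up to 10 kb. These sizes were chosen so the planted effects are
unambiguous (e.g. scattered-target MAD ≈ genome/4 ≈ 75 kb versus
prophage-confined MAD ≤ 20 kb) while a full run completes in well under a
minute; all stages scale linearly in subject length and pair count.

## Known limitations

- One called region per subject (min–max span): tandem or distant multiple
  prophages merge.
- The identity scan is gapless; indel-diverged duplicates below ~95%
  gapless identity on one diagonal will be missed.
- The repeat-anchored extractor requires the repeat to be known; it does
  no de novo repeat discovery and no array quality scoring.
- The permutation null conditions only on per-isolate spacer counts, not
  on spacer-frequency structure within modules.
- Known/new classification is exact full-length matching; near-identical
  spacers (1 mismatch) count as new.
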