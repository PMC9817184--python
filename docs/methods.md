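# Methods

## The inference problem

Given whole-genome short reads from a single putative hybrid individual
and assemblies for a panel of candidate parent species, infer (i) the two
parent species, (ii) which of them is the dam, and (iii) whether the
individual is an F1 or a first-generation backcross (BC1). The method
deliberately avoids genotyping: it relies only on counting which
reference each read matches best, plus a topology-only census of gene
trees.

## Balanced fragment database

Assemblies differ enormously in size and contiguity, which would bias raw
hit counts. Each species' genome is therefore partitioned into
non-overlapping 100-bp fragments (tiling starts at position 0 of each
contig; a terminal remainder shorter than one fragment is discarded) and
an equal number of fragments per species is sampled uniformly without
replacement. At full scale, 10⁶ fragments × 100 bp ≈ 10% of a 1-Gb
genome; on the small synthetic genomes used here all tiles are kept
(requesting more than exist clamps with a warning). Fragment ids are
`species|contig|start` (0-based, half-open). Only the forward strand is
stored; the aligner searches both strands of the query, which halves the
index without losing hits.

## Aligner and E-values

A self-contained seed-and-extend local aligner stands in for a
general-purpose search tool so that the whole procedure is reproducible
from one codebase:

* **Seeding.** An exact k-mer index (default k = 11, the classic
  nucleotide-search word size) maps every fragment k-mer to
  (fragment, offset) postings. For each read and strand, every shared
  k-mer becomes a seed on diagonal (fragment offset − read offset).
* **Extension.** For each fragment with at least one seed (configurable
  minimum), a banded affine-gap Smith–Waterman runs with band half-width
  15 around the best-supported diagonal. Scoring: match +1, mismatch −2,
  gap of length g costs 5 + 2g. Since the synthetic data contain
  substitutions only, optimal local alignments are gapless and lie on the
  seed diagonal, so the band never truncates the optimum; an exhaustive
  test against full-matrix Smith–Waterman (an independent implementation)
  enforces this on small databases.
* **Statistics.** Bit score S′ = (λS − ln K)/ln 2 with λ = 1.28,
  K = 0.46 — the published gapped Karlin–Altschul parameters for this
  scoring scheme — and E = m·n·2^(−S′), where m is the read length and n
  the total database length. Hits with E above a ceiling (default 10⁻³)
  are dropped. The census uses only the *ranking* of E-values, so modest
  inaccuracy in λ, K is immaterial.

**Best-hit rule.** Per read, the minimal-E alignment wins. If two or
more *species* share the minimal E (integer scores make this an exact
score tie; a relative bit-score tolerance of 10⁻⁶ is used when comparing
float bit scores), the read is discarded as a tie — multiple tied
fragments of the same species do not discard. Census proportions are
over uniquely assigned reads; tie and no-hit tallies are reported
alongside, and assigned + ties + no-hits equals the number of queries by
construction.

## Read quality control

Reads are Phred+33; the maximal 3′ run of bases below quality 30 is
trimmed, reads shorter than 30 bases after trimming are dropped, and
reads with more than 30 masked (N/lowercase) bases are dropped. The
simulator writes one constant quality per read encoding its mean error
rate, so for simulated data this stage is structurally a pass-through:
the full pipeline clamps the trim threshold to the simulated constant
quality (logged) because a constant quality below threshold would
otherwise delete every base — constant qualities are *plausible*
placeholders, not instrument profiles, and trimming them carries no
information.

## Dam assignment

The same census against a database of tiled whole mitochondrial genomes.
The dam is called when the top mito species reaches a 0.99 proportion of
mito-assigned reads *and* is one of the two nuclear-census parents;
otherwise the dam is ambiguous. The threshold mirrors the near-unanimity
expected of maternal inheritance while leaving slack for the occasional
spurious assignment of a nuclear read at small simulation scale.

## Gene-tree sister census

Each Newick gene tree is rooted on the edge subtending a named outgroup
leaf (trees lacking the outgroup are tallied as unrootable and skipped:
sisterhood is undefined without a root). The sister of the focal tip is
the leaf set of its parent's other children — under a multifurcating
parent, the union, hence non-singleton. Only singleton-sister trees
enter the proportion denominator; multi-leaf-sister trees are tallied
separately. Branch lengths are ignored. The top sister species being one
of the two census parents is reported as a concordance flag.

## Generation classification

With c₁ reads assigned to the dam-lineage parent and c₂ to the other,
exact two-sided binomial tests compare p̂ = c₁/(c₁+c₂) with 1/2 (F1) and
3/4, 1/4 (BC1 toward either parent), all at α = 0.001. F1 requires the
1/2 model retained and both backcross models rejected; a BC1 call
requires its model retained and the 1/2 model rejected; anything else is
ambiguous. Swapping c₁ and c₂ swaps the two BC1 outcomes and leaves
F1/ambiguous fixed.

**Effective sample size.** Reads are not independent draws of ancestry:
a BC1 genome carries its minority ancestry in O(number of chromosomes ×
crossovers) blocks, so the *realized* backcrossed-parent fraction varies
around 0.75 with SD ≈ 0.144/√C for C chromosomes with one crossover each
(≈ 0.032 at the default C = 20), vastly exceeding binomial noise at
20,000 reads (SE ≈ 0.003). Tests at raw n would therefore reject every
model for every real BC1. `ParentageModel` downsamples the counts,
proportion-preserving, to n_eff = 150 before testing. That value comes
from a variance argument: at α = 0.001 the exact-test acceptance region
at n = 150 (±≈0.11 around the null) comfortably contains the
block-induced ancestry dispersion while still separating 0.5 from 0.75
by several standard errors, giving ≥95% correct generation calls in the
seeded end-to-end suite. `classify_generation` itself tests whatever
counts it is given (n_max is an argument), and the raw counts are always
reported. The summary prints an explicit caveat.

## The simulator

What it emulates, and its defaults (all overridable in
`SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `genome_length` / `n_chromosomes` | 50 kb / 20 | nuclear genome, equal-length chromosomes |
| `mito_length` | 16 kb | one mitochondrial sequence per species |
| `species` | 2 parents at d = 0.05, decoys at 0.20, 0.30 | JC69 branch lengths from a uniform-random ancestor |
| `hybrid_cross`, `backcross_parent` | F1 | BC1 = backcross gamete + recombinant F1 gamete |
| `n_crossovers_per_chromosome` | 1 | uniform crossover positions in the recombinant gamete |
| `balanced_crossovers` | off | single midpoint crossover ⇒ recombinant ancestry exactly ½ |
| `read_length`, `n_reads` | 100 bp, 20,000 | single-end, uniform starts, random strand |
| `error_rate` | 0.005 | i.i.d. substitution errors; constant Phred = round(−10 log₁₀ e) |
| `mito_read_fraction` | 0.05 | fraction of reads drawn from the mitochondrion |

Species follow a star phylogeny: each species is the ancestor plus JC69
substitutions at observed rate p = (3/4)(1 − e^(−4d/3)), so a pair at
branch lengths d₁, d₂ behaves as a single branch of d₁ + d₂; the default
parents sit at ≈9.5% observed pairwise divergence. Reads carry their
true origin (majority parent over the span, or mito) in the header, and
hybrids carry a per-base origin track, so censuses can be compared
against construction. Gene-tree forests place the focal tip's sister
according to a category draw — a named species (singleton) or a two-leaf
cherry — either independently per tree (Bernoulli) or by exact quota;
remaining taxa form a shuffled ladder below, with the outgroup at the
base and unit branch lengths. Everything is deterministic under the
seed, down to bytes of FASTA/FASTQ/Newick output.

The default genome is 20 chromosomes rather than one: with a single
chromosome and one crossover, a BC1's realized ancestry is uniform on
[0.5, 1] and the 75% expectation is unrecoverable from any one
individual; 20 independently recombining chromosomes shrink the realized
SD to ~3 percentage points, which is what makes single-individual
generation classification meaningful at all. `balanced_crossovers` is
the deterministic analogue of quota tree sampling: it fixes the
recombinant gamete's ancestry at exactly ½ (hence total 75/25) for
fixture-grade tests, while the default random placement keeps the
realistic block-length variance.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: indels and structural variation (genomes
stay colinear, so tiling boundaries correspond across species and
cross-species misassignment is rarer than in practice), rate
heterogeneity and GC bias, repeats and low-complexity sequence,
instrument-realistic quality profiles, paired-end information,
incomplete lineage sorting in gene trees (sister categories are drawn,
not coalescent-simulated), and assembly error in the references.

## Fixture forest

The regression fixture for the tree census is an 8063-tree forest whose
sister categories are fixed by quota: 5910 singleton-sister trees of
which 2660 (45.0%) have the sire-lineage taxon as sister, 2009 (34.0%)
the dam-lineage taxon, 12 (0.2%) the cracid representative, the
remaining 1229 spread evenly over the other 14 taxa, plus 2153
multi-leaf-sister trees. It is generated programmatically
(`hybridcensus.fixtures.build_census_fixture`) with a seeded permutation
rather than shipped as a file; the sister census must reproduce the
sidecar counts exactly, by construction.

## Problem sizes and runtime

The default study scale — four species, 50-kb genomes, 2,000-fragment
nuclear database, 20,000 reads — was chosen so a full
simulate-to-call replicate runs in a few seconds and the complete test
suite (including 20 F1 + 20 BC1 end-to-end replicates and the 8063-tree
fixture) in a few minutes on one CPU, while keeping binomial standard
errors on census proportions below half a percentage point. The aligner
inner loops are numba-compiled.

## Known limitations

* Later generations (F2 intercrosses, BC2+) are out of scope; their
  expected shares overlap the tested models and would mostly come out
  ambiguous.
* The binomial framework treats parent-assigned reads as exchangeable;
  the effective-sample-size correction is a blunt (if conservative)
  answer to block-correlated ancestry, not a model of it.
* E-values are calibrated for the fixed scoring scheme only; changing
  scores without updating λ and K distorts absolute E (rankings, which
  the census uses, are unaffected).
* With quota sampling the fixture census is a construction, not an
  estimate; it validates bookkeeping, never inference.
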