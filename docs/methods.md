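# Methods

## The problem

In a panel of sequenced strains, a variant shared by several isolates can
reflect (i) a single emergence inherited by descent, (ii) independent
recurrence of the same substitution in separate lineages (homoplasy), or
(iii) an ancestral polymorphism maintained by balancing selection through
lineage splits. Distinguishing (i) from (ii)+(iii) from genotype data
alone is the package's core task; (ii) and (iii) are not distinguishable
per variant by this method, only in aggregate through simulation.

## Local phylogeny

Admixed genomes are mosaics of founder haplotypes, so no single tree
describes all loci. For each variant the pipeline builds a local tree
from a window of `W` variants centered on it (default `W = 500` variants;
a smaller `W`, e.g. 200, suits sparser panels). Conventions:

- Windows are truncated, never wrapped, at chromosome ends, and never
  cross chromosome boundaries (mosaicism is per-chromosome). The focal
  variant is part of its own window.
- Distances are raw missing-aware SNP differences: `d(i,j)` counts loci
  where both strains are called and differ. No per-pair normalization by
  default (an option exists on the identity track via its co-called
  counts).
- Neighbor joining (Saitou–Nei) with deterministic tie-breaking: taxa are
  processed in name-sorted order and Q-criterion ties join the lowest
  index pair. Negative branch-length estimates are clamped to zero. NJ is
  exact on additive matrices (property-tested to 12 taxa).
- Each local tree is midpoint-rooted: the emergence rules need a rooted
  binary tree and no outgroup exists within a window. Diameter and
  midpoint-edge ties break toward the lowest node indices; a zero-diameter
  window falls back deterministically to the first edge and the variant is
  flagged.

A clade too closely related and internally mosaic to resolve (e.g. a
wine-like clade of near-identical strains) can be collapsed to a single
pseudo-strain carrying its modal genotype (per-locus majority over
members, ties toward the reference allele); no emergence events are then
inferred inside the clade. The collapse is configuration-driven — a named
strain list — never hard-coded.

## Emergence inference

Given the rooted local tree and the variant's leaf genotypes (missing
leaves pruned by absorption), a post-order pass assigns each internal
node a state:

| children               | parent state | event counted |
|------------------------|--------------|---------------|
| genotype g, genotype g | g            | no            |
| genotype g, genotype h | event        | **yes**       |
| event, genotype g      | g            | no            |
| event, event           | event        | no            |

`n_events` is the number of counted events. The event–event merge rule is
deliberately conservative (it never inflates the count), which is one
reason the method *underestimates* true homoplasy; the other is that
emergences on sister branches are indistinguishable from one. The rules
are symmetric in ref/alt, so `n_events = 0` exactly when the called
leaves are monomorphic, a singleton always yields 1, and `n_events`
equals the binary Fitch small-parsimony change count whenever no
event–event merge occurs (exhaustively verified on all rooted binary
topologies with ≤ 8 leaves × all labelings).

A variant is **shared** when at least two strains carry the alternate
allele (counted before any clade collapse) and **apparently multiply
emergent** when `n_events ≥ 2`. Scan summaries report both the count of
such variants (the headline) and total events beyond the first, since
either reading of "multiple emergence events" may be wanted.

The genome scan runs these rules through a numba kernel with an
incrementally updated window distance matrix (O(S²) per variant for the
update plus one small NJ); variants whose minor-genotype count among
called strains is ≤ 1 have a closed-form event count (0 or 1) and skip
tree construction. The kernel path and the pure-Python per-variant path
are asserted equal in the tests.

## Simulators and what they emulate

All randomness flows through one injected `numpy.random.Generator`;
identical seeds reproduce results bit for bit.

**Random mutations.** Positions uniform over a 16-chromosome karyotype
with the real *S. cerevisiae* reference lengths (total ≈ 1.207 × 10⁷ bp;
scalable by one factor for fast tests); uniform base composition;
transition probability κ/(1+κ) with κ = 3 by default. Within one lineage
a site is hit at most once (reversion neglected; occupied sites are
redrawn). Allelic identity is resolved per site: the first event fixes
the ref/alt pair and a recurrent hit in another lineage re-creates the
same substitution — this keeps the matrix biallelic and makes "same site
mutated twice" synonymous with "same variant emerged twice".

**Admixed panels.** Five founders × 30,000 mutations; ten mosaics, each
from two distinct founders drawn uniformly, via one meiotic crossover per
chromosome (breakpoint uniform in bp over 1..L−1, left parent a fair
coin); then 10,000 further mutations in each of the 15 strains. That is
N_total = 300,000 logged mutation events (≈ 297,000 distinct loci after
homoplastic collisions, which occur at a rate of roughly
(Σᵢⱼ nᵢnⱼ)/G ≈ 3,400 cross-lineage site pairs). The truth log records
every event with its lineage and carrier count, so conservation (alt
calls = event propagations) and true homoplasy are checkable exactly.

**Balancing overlay.** `round(f_ancestral × N_total)` fresh loci
(positions redrawn against existing loci), each strain independently alt
with probability `MAF_balanced`. N_total counts mutation *events* (the
exact 300,000), not distinct loci. Loci where no strain drew the
alternate allele are kept (they are simply monomorphic and inert in all
analyses); balanced loci carry no origination event and are flagged in
the truth log.

**Neutral placement.** Variants land on a branch of a given tree with
probability proportional to branch length and propagate to all descendant
leaves — each variant is a single emergence by construction. Positions
are uniform over the genome (real variant density is not emulated).

**Inbred cross.** Two parental haplotypes (all-ref vs all-alt over
n markers, default 12,054 markers / 1,125 progeny) are intercrossed for
six rounds of in-silico meiosis, random pairs from the previous
generation each round, shrinking linkage blocks roughly as in a highly
inbred haploid cross. Phenotype = Σ effect × genotype + per-plate offset
(SD 0.25 by default) + replicate noise (SD 1.0); biological duplicates by
default, plates of 16 × 24. Planted effects default to 0.4/0.3/0.2
phenotype SD when none are given.

What the simulators do **not** emulate: real variant density and
mutational hotspots, indels and structural variation, selection during
the simulation itself (other than the balancing overlay), diploid
genetics beyond the meiosis abstraction, and ecological structure in the
niche labels. Passing tests therefore show that the inference machinery
behaves correctly under these idealized conditions, not that real panels
satisfy them.

## QTL → QTN mapping

Phenotypes are replicate means, Z-scored across progeny, so effects are
in phenotype SD. The design matrix appends non-genetic pseudo-genotypes
(per-plate membership shares, one level absorbed by the intercept;
scaled row/column positions); these compete in selection like any
predictor but are never reported as QTLs. Forward selection adds the
predictor with the best partial-F p ≤ 10⁻³ (sequential sums of squares;
ties toward the lowest genomic coordinate; collinear candidates are
skipped), then a leave-one-out screen drops terms with p > 10⁻⁵, worst
first, refitting. Variance explained is sequential (type-I) in selection
order over the total phenotype variance.

Fine mapping tests, for each candidate variant in the QTL's linkage
neighborhood (same chromosome, r² ≥ 0.5 with the selected marker by
default, or a bp window), the null "not causal relative to each nearby
alternative": the candidate is added to a model already containing the
alternative (plus the other model terms) and the worst-case nested-F
p-value over alternatives is taken. Only progeny whose genotypes separate
the two variants inform that test — the statistical analog of reciprocal
hemizygotes — so candidates in perfect linkage score zero and are never
resolved. The QTN score is −log10 of that worst-case p; its contract is
the ranking and the resolved/unresolved call (unique maximum, worst-case
p ≤ 0.05), not its absolute scale. FDR is estimated by rerunning the
entire selection on phenotypes permuted across progeny (≥ 10
permutations); with zero real QTLs the estimate is reported as 1.0 and
flagged degenerate.

## Selection tests

*Directional coherence.* QTL pairs are formed within trait and
chromosome, distance in marker units (≤ 500 by default, five equal bins);
a pair is coherent when both trait-increasing alleles come from the same
parent. Each bin reports the pooled fraction, the across-trait
mean ± s.e.m., and a two-sided binomial test against 0.5; a pooled test
across all pairs is also emitted (the per-trait and pooled readings are
both reported because either aggregation is defensible).

*Niche enrichment.* For variants carried by exactly two or three strains,
the observed fraction whose carriers share one niche label is compared to
neutral branch-proportional placement on the strain tree (50 replicates
by default). Because a branch's descendant set is fixed by topology, the
null needs only per-branch multinomial counts — an exact shortcut for
placing variants and counting, asserted equal to the matrix route in the
tests. Permutation p-values use add-one smoothing, (1 + #{null ≥ obs}) /
(reps + 1), and are never exactly zero. Variants in ≥ 4 strains are
excluded: too few niches have that many isolates for a fair null.

## Problem sizes

The default test suite exercises the full study conditions where they are
cheap (full-scale admixed builds and scans run in a few seconds each via
the incremental kernels) and 1/10–1/50-scale populations elsewhere; the
acceptance script runs the five-replicate balancing experiment at full
scale. The balancing sweep's replicate count defaults to 5 per parameter
combination, and the admixture validation to 25 replicates, both
overridable through `RunConfig`.

## Known limitations

- Small-scale (≪ full) populations inflate false multiple-emergence
  calls: a 500-variant window then spans a large fraction of a
  chromosome, so windows straddle crossover breakpoints far more often
  than at realistic density. Inference quality statements (the mild
  underestimate) hold at the full study conditions, not at aggressive
  down-scaling.
- At `MAF_balanced = 0.5` and 15 strains, essentially every balanced
  locus is inferred multiply emergent (its carriers are independent of
  the tree), so the inferred count under a heavy balancing overlay is
  close to the number of balanced loci plus the admixture baseline.
- Midpoint rooting of a noisy local tree can place the root inside an
  alt-carrying clade, splitting one emergence into two; this and
  breakpoint-straddling windows are the main false-positive modes.
- The cross simulator's pool mating is one of several defensible readings
  of "highly inbred"; linkage decay, not pedigree realism, is the
  emulation target.
- The directional test treats QTL effect signs as known without error;
  mapping uncertainty is not propagated.
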