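# Methods

## Coordinate conventions

All in-memory coordinates are 1-based inclusive, so a span's length is
`end − start + 1`. This convention is anchored by the focal-deletion sizes
the package must reproduce from printed coordinate strings: the three
reference spans measure exactly 180 kb, 356 kb and 267 kb only under
inclusive arithmetic. BED (0-based half-open) converts on read
(`start+1, end`) and back on write. Free-form coordinate strings are parsed
by stripping every non-digit character from the numeric tokens, which makes
the parser insensitive to comma grouping — including malformed grouping such
as `130,150,01` — and the result is invariant under any comma placement of
the same digit strings. Chromosome labels compare after stripping an
optional `chr` prefix. Kilobase rendering rounds half away from zero; raw bp
is always retained.

## Single-cell copy-number states

Per-cell integer CN lives on a uniform bin lattice (default 20 kb, so a
180-kb focal deletion spans 9 bins). Raw CN is kept in [0, 6]; the reporting
rule reduces values above four to four and flags them "≥4". The per-cell
state at a locus is the modal capped CN across the bins overlapping the
locus, ties broken toward the lower CN — conservative in the direction of
loss, the phenomenon of interest; a lower-median aggregation is available
behind a switch. Capping commutes with the modal vote (verified by
exhaustive enumeration over ≤4 bins with CN ∈ [0, 6]). State fractions use
all cells of the input matrix as the denominator; the pipeline does not
attempt tumor/normal discrimination, because the matrices it consumes are
assumed sorted (CD138⁺) — contamination is modeled, when desired, as an
explicit diploid clone in the generator.

## Clone decomposition and event-parsimony trees

Cells are clustered by average-linkage agglomeration on the mean per-bin
Manhattan distance between capped CN vectors, cut at a distance threshold,
with clusters under `max(3, 0.5%)` cells merged into their nearest cluster.
The threshold trades off noise against the smallest detectable event: on
the 250-bin preset genome a 9-bin focal deletion sits at distance 0.036
CN/bin from its parent clone while the noise floor at the default noise
model is ≈ 0.01, so preset analyses cut at 0.02. (The library default of
0.15 is appropriate for genomes where clones differ by arm-level events.)
All tie-breaks are deterministic — clones are labeled in order of smallest
member cell index — so cell order never changes the partition.

Consensus profiles take the per-bin mode (ties toward lower CN). An event is
a maximal run of consecutive bins within one chromosome whose child−parent
difference is a constant nonzero delta. The tree over {diploid root} ∪
clones minimizes total event count: exhaustive (vectorized) search over all
acyclic parent assignments up to 6 clones, greedy nearest-ancestor
attachment above that, ties preferring the smaller parent index. The root is
always the all-2 profile and clones are internal nodes, not only leaves, so
an ancestor clone with surviving cells is representable. Recurrent events on
different edges are not penalized.

Topology recovery is identifiable only when distinct clones differ by at
least two event segments: with single-segment edges, equal-cost rewirings
exist (parent→child and child→parent both cost 1), and the parsimony
optimum is not unique. The recovery suite therefore simulates clones with
two dedicated, non-adjacent event regions each; under those conditions
noise-free clustering + parsimony recovers the generating topology
essentially always (≥ 99/100 seeded runs).

## Bulk variant interpretation

The standard linear purity/CN mixture is used throughout (normal CN fixed
at 2; both target genes are autosomal):

    corrected VAF = raw · (p·CN_t + (1−p)·2) / (p·CN_t)
    multiplicity  = round(raw · (p·CN_t + (1−p)·2) / p), clipped to [1, CN_t]
    CCF           = raw · (p·CN_t + (1−p)·2) / (p·m), clipped to [0, 1]

`CN_t` may be fractional: when the locus CN is heterogeneous across
subclones (e.g. small biallelically deleted subclones inside a monoallelic
background), the fraction-weighted average CN makes the CCF estimator the
exact inverse of the forward mixture; rounding it instead biases CCFs
upward by the deleted fraction. Confidence intervals propagate a 95% Wilson
interval on the raw VAF through the same linear map. A variant is called
clonal at CCF ≥ 0.9 or when the CI reaches 1.0; the threshold is
uncritical because the events this pipeline classifies sit far from the
boundary (corrected VAFs of ~100% vs subclones at ≤ 45%).

Per-gene biallelic status combines allele-specific CN with protein-altering
mutations: total CN 0 → `biallelic_deletion`; one remaining allele
(CN 1, or minor allele 0 for copy-neutral LOH) plus a clonal
protein-altering mutation → `deletion_plus_mutation`; two mutations
established in trans on ≥ 2 copies → `compound_mutations`; one remaining
allele alone → `monoallelic_loss`; otherwise `intact`.

## Coding consequences

Annotation operates purely in CDS space. SNVs re-translate the affected
codon. In-frame deletions re-translate the whole protein and locate the
deleted residues via the longest common prefix of old and new proteins,
which automatically reports the 3′-most equivalent position inside
repeated-residue runs (the HGVS normalization rule); deletions whose length
is not divisible by 3 are routed to the frameshift annotator and vice
versa. Frameshifts re-translate from the first changed residue and emit
both the standard HGVS rendering (`fsTer k`, stop counted in the new frame
from the changed residue) and an absolute-residue-number rendering, since
published variant names sometimes use the latter; a shift that reaches no
stop is flagged `no_stop` rather than raised.

The bundled BCMA-like CDS is synthetic: 100 codons constructed from the
coding-level facts that matter (codon 27 = CGA; Ser29/Ser30 and Pro33/Pro34
as identical-codon repeats; Thr32), with alanine filler. It is not the real
transcript, and tests that use it check codon arithmetic and normalization
behavior, not transcript biology. The domain map (extracellular 1–54,
transmembrane 55–77, intracellular 78–100) is likewise a fixture layout.

## Mutual exclusivity and convergence

For a variant pair with read-pair counts (rr, ra, ar, aa) and per-read
error rate ε, the expected error-driven double-alternate count is
λ₀ = ε·(ra + ar) + ε²·rr. The pair is *co-occurring* if a one-sided Poisson
test of aa against λ₀ gives p < 0.01; *exclusive* if aa is within the 99th
percentile of Poisson(λ₀) and each variant has ≥ 3 solely-supporting pairs;
otherwise *indeterminate*, and a call requires ≥ 10 informative pairs.
These thresholds are this package's choices; the calls are symmetric under
swapping the pair.

Convergence over one gene requires ≥ 2 inactivating events, every phased
pair exclusive, and — for pairs without phasing, which is always the case
for CN-defined events — a joint pigeonhole fit: Σ CCF ≤ background CCF +
tol (tol = 0.05, which keeps a configuration summing exactly to the
background compatible). Any co-occurring pair collapses the verdict to
`single-route`; failed pigeonhole or indeterminate phasing yields
`indeterminate`. The unexplained fraction is
`max(0, background − Σ CCF)·100`. Subclone fractions of CN-defined events
(focal biallelic deletions, translocation disruptions) are consumed as
given inputs, as they come from WGS/SV analysis rather than read phasing.
Because the pigeonhole slack is 0.05, verdict recovery on simulated
cohorts needs CCF measurement noise well inside that slack (sd ≈ tol/3);
the recovery suites use an effective depth of 2,000, the precision a real
analysis reaches by pooling the variants of each subclone.

## Synthetic cohort generator

The generator resolves a declared clone tree (rooted at an implicit diploid
"normal") into per-clone per-bin CN profiles, then simulates:

- **cells**: clone membership multinomial in the declared fractions; per
  bin, reads ~ Poisson(λ·bias_b·CN/2) with a fixed per-bin lognormal bias
  (σ default 0.05) standing in for all systematic coverage effects (no GC
  model); observed CN = `round(reads/(λ·bias_b)·2)` clipped to [0, 6].
  λ defaults to 100 reads/bin; an infinite-λ sentinel gives exact,
  noise-free CN, used as the zero-noise oracle throughout the tests. At
  (λ = 100, σ = 0.05) the per-bin mis-call rate on diploid bins is ≈ 1.5%
  (the exact Poisson-tail value; the tests assert agreement with that
  oracle). Doublets and replicating cells are not simulated — the upstream
  instrument pipeline filters them.
- **bulk reads**: expected VAF from the mixture formula above with the
  declared purity, alt counts binomial at the requested depth.
- **phased pairs**: each pair samples a tumor clone by fraction and one
  chromosome copy at the locus; a copy carries a variant according to the
  clone's multiplicity and copy-offset (overlapping copy ranges = cis,
  disjoint = trans); each of the two reads flips with probability ε
  (default 10⁻³). Purity enters bulk VAFs but not phasing, which models
  reads from sorted cells.

Preset scenarios fix the published clonal architectures as generator truth:
`MM1-like` (monoallelic focal deletion in 2.1% pre; 86.8% biallelic /
2.1% monoallelic-only / 11.1% unaltered post), `MM2-like` (monosomy 16 in
92.4% with a nested biallelic subclone at 0.8% pre, sweeping to 99.5%
post), `MM31-like` (chr12p-deleted background with four mutually exclusive
inactivating subclones at 45/28/12/15%), `MM32-like` (two exclusive
subclones at 35%/7%, leaving 58% with no biallelic event) and
`null-diploid`. They live on a compact synthetic genome (chromosomes of
1–2 Mb, 250 bins total) with target loci at synthetic coordinates; clone
fractions, purities and event nesting — not genome size — are what the
downstream statistics see, and the published focal sizes are exercised
separately through real coordinate strings. Preset cell counts are 2,000
per timepoint, matching the scale at which a 0.8% subclone is detectable
(expected 16 cells) while keeping simulation and clustering fast.

What passing these simulations does *not* show: robustness to GC-dependent
coverage waves, segmentation artifacts at event boundaries, doublets,
S-phase cells, or mis-specified purity — real data add all of these on top
of the modeled Poisson/lognormal noise.

## Numerical choices and degenerate inputs

Ties in modal votes go to the lower CN everywhere (locus states, consensus
profiles). Clustering of an all-identical matrix yields one clone (not an
error); a single cell is an error. Fraction tables must sum to 100% within
0.5 points. The fish-plot table reports fractions and parentage only;
between-timepoint interpolation is left to the renderer. Pipeline runs are
deterministic given config + seed (verified byte-identical in tests), and
every number in the combined escape report equals the corresponding stage
artifact's value.

## Problem sizes used by the checks

The acceptance suite simulates 20 seeds × 2,000 cells/timepoint for
fraction recovery, one 2,000-cell noise-free matrix for exact clustering,
100 noise-free cohorts (150 cells, 2–5 clones) for topology recovery,
100 random ≤ 6-clone instances for the exhaustive-parsimony oracle, and
500 variants at depth 100 for CCF recovery. The CCF-recovery benchmark is
defined in the regime the classified escape variants occupy — mutations
coupled with monoallelic loss (CN_t = 1, m = 1) in a sorted, effectively
pure sample, where CCF equals VAF — because there the binomial noise at
depth 100 maps to a CCF RMSE of ≈ 0.042; on heterozygous-diploid subclonal
cohorts the same depth gives ≈ 0.065 irrespective of implementation.
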