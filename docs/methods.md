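# Methods

This note documents the models, estimators and design choices behind
`mseqevo`, and what its simulation-based verification does and does not
demonstrate.

## Observation model

A tumour is a mixture of a normal-cell fraction `1 − p` and cancer cells
partitioned among the clones of a rooted lineage tree. Each mutation
belongs to one clone; the cancer-cell fraction (CCF) of a clone in a
region is the fraction of that region's cancer cells in the clone's
subtree. For a mutation carried on `m` chromosome copies in a region with
purity `p`, clone CCF `c`, and bulk total copy number `CN_t` at the locus,
the expected variant allele frequency is

    E[VAF] = p · m · c / (p · CN_t + 2 · (1 − p)).

Reads are Binomial(depth, E[VAF]) with depth ~ Poisson(mean depth). The
whole analysis — CCF estimation, clustering, tree building — treats each
(mutation, region) pair as one such observation; no read-level structure
is modelled.

Assumptions worth naming: one multiplicity per (mutation, region) — i.e.
copy-number events are approximated as clonal within a region (an event is
shown in a region's segment profile when the carrying clone's subtree CCF
exceeds 0.5 there); the matched normal is diploid at every locus; regions
are statistically independent given the clone mixture.

## Filtering

Quality filters run in a fixed order so each rejected site carries one
deterministic reason: sex chromosome → tumour depth (< 70 in any region) →
germline depth (< 20) → germline evidence. Germline evidence rejects only
when *both* the germline VAF exceeds 2% *and* the germline alt count
exceeds 2. The panel-of-normals filter rejects a site when the fraction of
panel normals with VAF ≥ 2% is ≥ 20%. Two-tier calling keeps a mutation
when some region reaches VAF ≥ 5% (boundary inclusive) and calls
per-region presence at VAF strictly above 2.5% ("exceeds"); the asymmetric
boundary conventions are pinned by tests. Zero-depth regions count as
VAF 0 and are logged. Read-level QC (mapping/base quality, strand bias)
belongs to upstream callers; the corresponding thresholds are recorded in
`FilterParams.provenance` for provenance only.

## Copy-number metrics

Ploidy is the segment-length-weighted mean of the unrounded total copy
number. wGII is computed per autosome as the fraction of *covered length*
(not segment count, which would depend on arbitrary breakpoints — pinned
by a split-invariance property test) in segments whose rounded integer CN
differs from the rounded ploidy, averaged without weighting over the
autosomes present; autosomes absent from a profile are excluded from the
mean and logged rather than counted as zero. The CIN call is strict:
wGII > 0.2. LOH at a gene means minor copy number 0 with at least one
copy retained, assessed at the gene midpoint; a gene outside segment
coverage is reported unassessable.

## CCF estimation

`MUT_CN = VAF · (1/p) · (p·CN_t + 2(1−p))` converts a VAF into mutant
copies per cancer cell. Multiplicity uses the nearest-integer rule
clamped to `[1, CN_major]`, and `CCF = MUT_CN / m`, reported capped at 1
with the raw value retained. This estimator is the constrained MLE per
observation and is exact in noiseless limits. The clonal threshold is
CCF ≥ 0.7, inclusive (the alternative strict convention appears in some
descriptions; the inclusive form is used consistently here, including for
single-region clonal loads).

At 200× depth the per-observation error is dominated by binomial noise:
σ(CCF) = (p·CN_t + 2(1−p))/(m·p) · sqrt(v(1−v)/depth). Averaged over
purities 0.3–0.9 and the default clone structure this floor sits at a mean
absolute error of ≈ 0.05 — the verification target is met essentially at
the information limit, and individual seeds can land marginally on either
side of it. Cluster centroids, which average hundreds of observations,
are an order of magnitude more precise.

## Gain timing

A gain is timed from ubiquitous mutations inside the gained segment: if a
gain happened before most mutations accrued, (almost) none of them sit on
all copies of the gained allele, so the fraction at full multiplicity
(`m = CN_major`) is near zero. The label is *early* when that fraction is
≤ 5% (operationalising "near-complete absence"; configurable), *late*
otherwise, and *unassessable* below 10 informative mutations.

## Clone-tree reconstruction

Clustering proceeds in three stages:

1. **Presence patterns.** Mutations are grouped by their per-region
   presence calls (CCF > 1e-4 ⇒ present).
2. **Within-pattern splitting.** Each pattern group is split by a
   Gaussian-mixture model over CCF profiles with BIC model selection
   (k = 1…5, diagonal covariances, deterministic initialisation); a split
   is rejected when component centroids come within 0.1 (Chebyshev) of
   each other, since clusters inside measurement tolerance are one clone.
   Fixed-distance agglomeration on single-mutation profiles was evaluated
   and discarded: per-observation CCF noise (~0.1 per region at 200×)
   swamps any threshold that can still separate clones 0.2 apart.
3. **Dropout absorption.** Presence is a thresholded call, so a clone
   sitting near the detection limit sheds mutations into spurious
   sub-patterns (a binomial-tail effect, ~5–20% per region at CCF ≈ 0.2).
   A cluster is therefore absorbed into a larger one when its pattern is a
   subset of the larger cluster's, centroids agree (≤ 0.1) on its present
   regions, every missing region has larger-cluster CCF ≤ 0.25 (dropout
   plausible), and it is a minority (≤ 1/3) of the merged cluster — a
   similarly sized group is treated as a distinct clone.

Clusters below 8 members dissolve into an unassigned list, except that a
small cluster containing a flagged driver mutation may be retained (small
driver-bearing clusters are biologically meaningful even when too small
for the clustering to support).

The tree is rooted at the germline (CCF 1 everywhere). A node may parent
another only if it contains the child's presence regions *and* dominates
its CCF per region within slack ε = 0.1. The error score of a tree is the
summed positive part of (children's CCF sum − parent CCF) over nodes and
regions. Trees are ranked by (i) a *soft* error that forgives violations
up to 0.05 per (node, region) — centroid noise at sum-rule equality, which
occurs generically when a parent has no private cell population in a
region; (ii) total parent–child L1 distance ("tightness", a parsimony
preference for the closest dominating ancestor — an ancestor's profile
always dominates an intermediate parent's, so the true parent is never
looser); (iii) the exact error; (iv) the lexicographic edge list. The
reported `error_score` is always the plain positive-violation sum. The
search is exhaustive for ≤ 12 clusters (verified against an independent
brute-force enumeration in the tests) and greedy with hill-climbing
beyond. If no tree meets the slack, the best-effort tree is returned
flagged invalid rather than raising.

## Conflicts and parallel evolution

A conflict is a mutation absent from a region where its clade is present.
Each mutation is mapped to its most plausible clade: candidate nodes must
cover the mutation's presence regions and match its CCFs (≤ 0.15
Chebyshev on present regions), and a candidate with extra regions stays in
the running only if each absence there is either loss-supported (locus
total CN strictly lower than the minimum CN across the mutation's present
regions) or dropout-plausible (candidate CCF ≤ 0.25). Among plausible
candidates the largest wins — this is what lets mutations deleted by a
regional copy loss rejoin their parental clone — otherwise the mutation
keeps its own cluster. A conflict is `explained_by_loss` exactly when the
CN-drop condition holds; an uncovered locus is unexplained and logged.

Parallel evolution reports genes with driver-flagged mutations on two or
more distinct branches: *parallel* when at least two branches are mutually
non-ancestral, *trunk_and_branch* when they form an ancestral chain
(progressive inactivation); identical protein changes (or identical
residue positions) on distinct branches set the same-residue flag.

## Mutational signatures

Spectra are tabulated over the 96 pyrimidine-frame trinucleotide
substitution classes in canonical order (`A[C>A]A … T[T>G]T`);
purine-reference substitutions are reverse-complemented, indels excluded,
contig-edge sites (no flanking base) excluded and logged. Refitting
normalises the spectrum to frequencies and solves a nonnegative least
squares problem against the catalog columns — with cutoff 0 this matches
iterative forward-selection refitters up to numerical tolerance while
being deterministic and convex; a nonzero cutoff zeroes small weights and
rescales the remainder. Reporting masks signatures below 5% in every
analysed group. Trinucleotide-abundance correction between genome and
exome frames is intentionally not applied (no normalisation target is
defined for the toy genome); spectra are compared within one frame.

The default catalog is synthetic: 30 probability columns shaped like a
standard 30-signature catalog, with three crafted columns mimicking
CpG-deamination-like (S1), broad C>T (S6) and G-flank C>T/C>G (S15)
processes, the rest sparse Dirichlet draws. Tests additionally use
orthogonal catalogs. Conclusions about recovery therefore concern the
refitting machinery, not any real catalog's collinearity structure —
recovery of highly collinear real signatures will be correspondingly
noisier.

## dN/dS

The opportunity model enumerates all 3L single-base substitutions over the
supplied in-frame coding sequences, each labelled synonymous or
non-synonymous and assigned to one of 96 context classes plus an edge
class for flankless sites; totals are conserved at exactly 3 per site.
Sequences with internal stop codons are excluded (the simulator's toy
genes are generated stop-free from sense codons so this rule never empties
the model on simulated data). With observed counts `s_c, n_c` and
opportunities `L_S,c, L_N,c`, the model is
`s_c ~ Pois(λ_c L_S,c)`, `n_c ~ Pois(ω λ_c L_N,c)`; the per-context rates
λ_c are profiled out and ω is the profile-likelihood MLE (for a single
context class this reduces to the familiar `(n/L_N)/(s/L_S)`). The 95% CI
is the χ²(1) likelihood-ratio profile; with zero non-synonymous counts the
estimate is 0 with an upper bound only, and zero synonymous counts leave
the ratio undefined (flagged, never imputed). The 96-class strand-collapsed
rate model (rather than 192 classes with per-gene random effects) fits the
intended use: global per-compartment ratios, not per-gene discovery.

## Single-region vs multi-region comparison

Per region: total mutation load, clonal load (CCF ≥ 0.7) and the
tumour-wide ubiquitous load, with percent differences relative to the
ubiquitous load. The illusion of clonality counts (mutation, region)
observations where a tumour-wide heterogeneous (shared or private)
mutation reaches CCF ≥ 0.7 in that region; driver-level percentages are
over driver-flagged observations, per gene and overall. Multi-allelic
sites are not deduplicated (each retained row counts once).

## The simulator

The generator emulates the data regime this analysis targets: ~7 regions
(optionally lymph-node samples seeded from a single subclone), a long
trunk (default 700 truncal mutations) with 1194 branch mutations across a
six-clone tree, trunk and branch substitutions drawn from different
signature mixtures over a toy 22-autosome genome (30 kb per chromosome,
coding tiles of sense codons named after recurrently mutated driver
genes), 27% context-free indels, per-region purity uniform on 0.2–0.9,
Poisson 200× depth, an optional per-base error rate (default 0.1%) so
filter specificity is testable, optional matched-normal contamination
(default 0), allele-specific events (default: early chr8 gain, late chr20
gain, truncal chr17 LOH, subclonal chr18 loss deleting previously acquired
mutations), and a 14-normal panel with recurrent artifact sites (2% of
sites, 30% carrier prevalence).

Regional clone mixtures are Dirichlet draws over 1–3 resident clones per
region (each non-root clone homed to a region, parents occasionally
co-resident), which yields the spatially ordered structure where
phylogenetically close clones co-occur. Mixtures are redrawn until every
present clone's CCF clears a floor (default 0.15) and clone profiles are
pairwise separated (default 0.1, raised to 0.2 in tree-recovery studies);
these constraints make identifiability explicit instead of leaving it to
chance. The lineage sum rule holds by construction (subtree sums of
nonnegative occupancy fractions).

What the simulator does *not* model — and hence what passing tests do not
show about real data: read-level artifacts (mapping error, strand bias,
FFPE damage), overdispersed coverage, subclonal copy number within a
region, germline variation, kataegis/clustered mutations, real exome
trinucleotide composition, and real-catalog signature collinearity.

## Verification problem sizes

The end-to-end checks run at deliberately desk-scale sizes: ~1,900-site
tumours; 50 tree-recovery replicates (4–8 clones, 7 regions, separation
0.2, purity 0.5–0.9); 200 neutral dN/dS replicates of 500 mutations;
100 signature-refit replicates of 1,000 draws; 3 gain-timing tumours with
10 timed gains each. A full pipeline run takes ~15 s on one CPU.

## Known limitations

- CCF error per observation is at its binomial floor (~0.05 mean absolute
  error under the default purity range); per-mutation CCFs at low purity
  should be read through cluster centroids.
- The clone tree is identified only up to the information in regional CCF
  profiles; clones with everywhere-equal profiles (a parent with no
  private cell population anywhere) are merged by construction.
- Gain timing assumes at most one gain per lineage path per locus and
  reads timing only off ubiquitous mutations.
- The dN/dS compartments come from presence categories, not from the
  fitted tree; mutations unassigned by the tree still contribute to their
  category's compartment.
- `error_score` values are comparable within this implementation only;
  other sum-rule tools scale their scores differently.
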