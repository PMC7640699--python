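# Methods

## Scope and data model

`metpair` compares paired primary tumors and distant metastases from
the same patients. Inputs per patient are a somatic mutation table with
tumor and matched-normal read counts (MAF-like TSV or VCF with `AD`),
copy-number segments (SEG, log2 tumor/normal ratio), phased
heterozygous-site allele counts, gene expression and promoter
methylation matrices, and sample metadata including tumor purity.
Purity and ploidy estimation, alignment, and variant calling are
upstream of this package: their outputs are its inputs. Coordinates are
1-based inclusive everywhere; chromosome names are normalized by
stripping a leading `chr`.

## Somatic mutation filtering

Kept mutations satisfy, in this order of evaluation: tumor depth ≥ 50;
normal depth ≥ 30; tumor VAF ≥ 5% for SNVs and ≥ 10% for indels
(VAF = alt/depth); normal VAF < 1%; population allele frequency ≤ 1%.
Boundary comparisons follow the inequality symbols exactly, so a record
at tumor depth 50 with VAF exactly 5% is kept and a normal VAF of
exactly 1% is removed. A missing population frequency is treated as 0 —
removal requires positive evidence of commonness. Each removed record
carries the first failing rule, so removal reports are deterministic.
Tumor mutation burden is the raw count of distinct filtered mutations
per sample (no per-megabase denominator is imposed). Canonical
cancer-gene mutations are those matching a user-supplied catalog of
previously reported changes, or disrupting events (stop-gain, splicing,
frameshift indel) in a cataloged tumor suppressor.

## CCF estimation and joint clustering

The CCF of a mutation with VAF *v*, purity ρ, local total tumor copy
number *C*ₜ and multiplicity *m* is
`v (ρ Cₜ + 2(1 − ρ)) / (ρ m)`, capped at 1. Local copy number comes
from the containing segment; the observed segment ratio is de-mixed
with purity (CN = 2(r − (1 − ρ))/ρ, rounded) and defaults to 2 when a
locus is uncovered. Multiplicity is estimated per sample by rounding
the fully-clonal solution and clamping to [1, Cₜ]; it is estimated per
sample rather than per mutation because a gain private to one sample
legitimately changes the number of mutated copies there. A mutation
absent from a sample (0 alt reads with depth ≥ 20) has CCF 0 there;
only SNVs enter clustering (indel VAFs are noisier), while indels still
contribute to distances and sharing statistics.

Joint clustering replaces a Dirichlet-process sampler with a
deterministic finite binomial mixture: cluster *k* carries a latent CCF
φₖₛ per sample; a member's alt count in sample *s* is
Binomial(depth, cᵢₛ φₖₛ), with cᵢₛ the CCF→VAF scale factor above. EM
uses a pooled-count update φₖₛ = Σᵢ rᵢₖ aᵢₛ / Σᵢ rᵢₖ dᵢₛ cᵢₛ (the exact
M-step when cᵢₛ is constant within the cluster, which holds at CN 2,
m 1, and a good approximation otherwise), k-means++-style seeded
initialization on naive per-mutation CCFs, 10 restarts, and K = 1..8
selected by BIC with K·S + (K − 1) free parameters. Clusters smaller
than 5 mutations — the conventional floor for an interpretable clone —
are dissolved and members reassigned to the nearest surviving cluster,
whose CCFs are then re-estimated from pooled counts. The whole fit is
deterministic given its seed. The clonal cluster of a sample is the one
with maximal mean CCF (ties: larger size, then lower id).

## Seeding mode, pigeonhole checks, parsimony trees

A cluster is *shared* when its mean CCF is at least `min_shared_ccf`
(default 0.05, below typical CCF noise at 200× depth) in both samples.
The pair is monoclonal iff the only shared cluster is the founding
cluster (the one clonal in both samples); any additional shared
subclone makes it polyclonal. No shared cluster at all violates the
common-ancestry assumption of paired tumors and raises an error rather
than returning a call. Sibling feasibility follows the pigeonhole
principle with a 0.05 tolerance: clones a and b can be siblings under
parent p iff CCFₐ + CCF_b ≤ CCF_p + 0.05; violations imply nesting.

The mutation partition of a pair (shared / primary-only /
metastasis-only) counts a mutation as present in the other sample if it
was kept there, or — rescue rule, on by default — if the other sample's
raw record shows ≥ 2 alt reads; this prevents single-sample filter
flicker from inflating private calls.

Phylogenies over ≤ 8 samples use the binary presence matrix with the
normal as all-zero outgroup: all (2k − 3)!! unrooted topologies are
enumerated and scored by Fitch parsimony (vectorized over columns with
state bitmasks); branch lengths count the mutations assigned to each
branch by a top-down pass that keeps the parent state whenever
possible. An independent oracle test checks the score against R
phangorn on a random matrix.

## Genetic distances

Over the union mutation set (absent → CCF 0): Nei's distance
`−ln[Σ(xᵢyᵢ + (1−xᵢ)(1−yᵢ)) / sqrt(Σ(xᵢ² + (1−xᵢ)²)·Σ(yᵢ² + (1−yᵢ)²))]`,
mean absolute difference `Σ|xᵢ − yᵢ|/n`, and Jaccard
`Σ(xᵢ−yᵢ)² / (Σxᵢ² + Σyᵢ² − Σxᵢyᵢ)`. Multi-region data are summarized
by the unweighted mean over all pairwise combinations. Degenerate
cases: identical vectors give 0 in all metrics; fully disjoint binary
vectors give Nei = ∞ (with a warning) and Jaccard = 1; Jaccard is
undefined (error) for two all-zero vectors.

## Signature refitting

Substitutions are encoded on the 96 pyrimidine-centered trinucleotide
channels (substitution-major order C>A..T>G × 4×4 flanking bases);
purine-centered records are reverse-complemented, non-SNVs excluded.
Exposures of a user-supplied column-stochastic signature matrix are fit
to the normalized catalog by NNLS; weights below the minimum
contribution (default 0.06, the convention of established refitting
tools) are iteratively zeroed with refitting on the surviving set, then
renormalized to sum 1. Reconstruction quality is the cosine similarity
between the catalog and its reconstruction. Category comparisons
(shared vs primary-only vs metastasis-only) include only patients with
strictly more than 50 mutations in every category — small catalogs give
unstable exposures — and use paired two-sided Wilcoxon signed-rank
tests; the test choice is this package's own and p-values are not
directly comparable to analyses using other tests.

## SCNA concordance

Genes take the log2 ratio of their containing segment
(coverage-length-weighted mean when spanning several; 0, flagged, when
uncovered), giving every sample values over one shared gene universe.
Calls use inclusive thresholds at ±log2(1.5). The purity adjustment
log2((r − 1)/ρ + 1) is applied gene-wise, to both samples of a pair,
only when either sample's unadjusted value passes the threshold — at
moderate purity this leaves single-copy events below threshold
untouched, which is a property of the rule, not a bug. Under the
standard purity-mixture model r = ρ·CN/2 + (1 − ρ) the adjustment
recovers CN/2 exactly (verified numerically to machine precision).
Adjusted ratios ≤ 0 (deep losses at low purity) are clamped to 1/64
with a warning. Trunk events carry the same non-neutral call in both
samples; discordant directions at one gene count as one private event
in each sample. Burdens are per-sample gain and loss counts;
cross-profile concordance uses Spearman correlation of per-patient
shared fractions.

## Allelic imbalance

At a phased het site, the direction of the allele-count deviation is
mapped through the phase label to a haplotype; sites with equal counts
are uninformative. Over a region, the statistic is the
majority-haplotype deviation count k of n informative sites, tested
against concordance 0.5 with the exact upper-tail binomial p =
P(X ≥ k | n, 0.5) at α = 1e-4. Taking the maximum over the two
haplotypes makes the effective null size ≈ 2·P(X ≥ k*), ≈ 9e-5 at
n = 50 — within the 2×10⁻⁴ budget. Detection scans sliding windows of
50 informative sites at 50% overlap, merges overlapping significant
windows, and re-tests merged spans; chromosomes with fewer informative
sites than one window are tested whole, with a warning. Sharing of an
event across the patient's samples re-applies the same test to each
other sample's sites over the event span. Segment labels are assigned
on the atomic intervals obtained by splitting the union of all event
intervals at every boundary (the package's resolution of cross-sample
boundary reconciliation): normal (no sample), norm-specific (normal
only), trunk (primary and metastasis), met-specific (metastases only),
private (exactly one tumor sample, a primary), shared (several but not
all tumor samples). Burdens are the event count and total affected bp.

## Expression, immune score, methylation

Raw counts are normalized as log2(10⁶·count/library + 1) and z-scored
per gene (constant genes dropped with a warning). The immune score is
the unweighted mean z-scored expression of a 40-gene panel; the panel
(cytolytic markers, HLA, IFN-γ pathway, chemokines, adhesion) is a
user input — the package ships only a synthetic placeholder panel for
tests, and deliberately does not guess the published gene list.
Variable genes have across-sample SD strictly > 2.0 on the log scale.
Sample clustering is complete-linkage agglomerative on 1 − Pearson
correlation with lexicographically sorted columns for determinism.
Methylation–expression coupling keeps genes with per-gene Spearman
ρ ≤ −0.5 across shared samples (constant rows excluded); paired
differential methylation uses two-sided Wilcoxon tests per gene with
Benjamini–Hochberg adjustment, requiring ≥ 4 pairs.

## Synthetic cohort generator

The generator defines the package's study conditions: a 10-chromosome
toy genome of 10 Mb each with 1,000 evenly spaced genes and 40
copy-number segment slots. Per patient it draws a clone tree (trunk CCF
1 in both tumor samples; subclones in predefined CCF slots 0.20–0.30
and 0.50–0.65 per sample, so sibling CCFs never exceed the parent's and
all clusters are ≥ 0.2 apart — the regime where subclonal
reconstruction from 200× exomes is expected to work; polyclonal mode
places one subclone at CCF 0.25–0.45 in both samples), Poisson(40)
mutations per clone, alt counts Binomial(200, expected VAF) with the
CCF→VAF model above, fixed normal depth 100 with 0 alt reads, and
contexts sampled from each clone's signature mix over the 96 channels
(no reference genome needed). The trunk mix is enriched by δ = 0.4 on
the first synthetic signature relative to private clones, emulating an
early mutational process. SCNA events occupy whole segment slots — 6
trunk, 2 primary-specific, 2 metastasis-specific by default (trunk
fraction 0.60) — with gains at CN 4 and losses at CN 0, the aberrations
whose unadjusted ratios pass ±log2(1.5) at purity 0.6 and therefore
trigger the conditional adjustment; emitted ratios follow
r = ρ·CN/2 + (1 − ρ) exactly. Truncal mutations on gained segments take
multiplicity 1 or CN − 1 uniformly (they may predate the gain);
subclonal mutations always multiplicity 1; no mutations are placed on
homozygously deleted segments. AI regions (150 contiguous sites of 300
per chromosome, read depth 50) emit deviations toward the event
haplotype with probability 0.85 (one trunk region, one
metastasis-specific; elsewhere the hap-0 allele count is
Binomial(50, 0.5), making direction a fair coin conditional on
informativeness). Metastasis immune-gene means are scaled by 0.5
relative to the primary; 40 of 120 methylation genes carry beta values
anti-correlated with expression (1 − min-max-scaled log expression plus
N(0, 0.02) noise). All randomness flows from one `numpy` generator per
patient, with per-patient seeds spawned from the cohort master seed, so
cohorts are byte-identical across reruns.

What the generator does **not** emulate — and hence what passing tests
do not certify on real data: sequencing error and strand artifacts,
mappability and capture-bias variation in depth, subclonal copy number
and whole-genome doubling, kataegis/clustered mutations, phasing
switch errors, batch effects in expression/methylation, and realistic
genome annotation. Results on real cohorts additionally depend on the
quality of upstream calling, purity estimates, and phasing.

## Benchmarks and problem sizes

`scripts/acceptance.py` and the acceptance test suite evaluate, with
fresh simulations per run: hand-derived distance values (to 1e-6) and
brute-force agreement on 10⁴ random vectors (1e-12); cluster-CCF mean
absolute error and model-order accuracy on 200 mixed-mode patients;
seeding accuracy on the same 100 + 100; noiseless signature recovery
(L1 ≤ 1e-6), cosine ≥ 0.95 rate over 200 Poisson replicates at n = 500,
and δ recovery on 14 monoclonal patients simulated at 150 mutations per
clone so every category clears the > 50-mutation eligibility floor;
AI-test size and power over 10⁵ regions of 50 sites; the SCNA
adjustment identity over a 9 × 5 purity × CN sweep and trunk-proportion
recovery; the 12-row filter boundary table; and end-to-end
shared-fraction recovery on the default 8-patient cohort. These sizes
keep a full run under a minute on one CPU while leaving the Monte Carlo
error of each rate well inside its acceptance margin.

## Known limitations

Exhaustive parsimony search is factorial in sample count (capped at 8).
The EM mixture assumes well-separated clusters and binomial counts;
overdispersed real data may need a beta-binomial extension. The
multiplicity heuristic can mis-scale CCFs of subclonal mutations on
multi-copy alleles (a known identifiability limit of CCF estimation).
The AI scan is a documented simplified stand-in for hidden-Markov
detectors and reports site-index windows, not breakpoint-resolved
events. TMB is a raw count, so cross-assay comparisons need a common
capture footprint.
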