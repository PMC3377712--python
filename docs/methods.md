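# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package. It is the reference for *why* each piece works
the way it does; the README covers what the package is for.

## Coordinate system: trees, edges, positions

All placement and mass arithmetic happens on a rooted reference tree whose
edges carry unique integer ids (preorder-assigned unless a jplace file
supplies its own numbering) and non-negative branch lengths in
substitutions/site. Two position conventions coexist and are converted
explicitly: jplace attachments measure `distal_length` from the edge's
leafward node (the jplace convention), while mass maps and all internal
integrals measure positions from the proximal (rootward) node. Path
distance between two points includes the partial edge segments at both
ends and is computed through the deepest common ancestor.

## Read QC

Reads are retained when they (1) start with a known barcode, (2) carry the
exact 16S portion of the reverse primer immediately after it, (3) keep at
least 200 nt once barcode and primer are trimmed, and (4) have a mean
Phred quality of at least 35. The mean-quality wording in the field is
sometimes given as a "-log10 quality score"; per-base Phred scores are the
only quality in a FASTQ, so criterion 4 is interpreted as mean Phred ≥ 35,
computed on the trimmed read. Retained reads are then clipped to the
longest contiguous span in which every 30-mer sub-window has ≥ 90% of
bases above Q15 (spans shorter than one window are evaluated as a single
window; ties go to the leftmost span), and the length criterion is
re-checked after clipping. Discards are attributed to the *first* failing
criterion, which makes the report comparable across runs; filtering is
order-independent by construction.

## Reference curation

Pairwise distance is the fraction of non-identical nucleotides over
comparable columns: any column where either sequence has a gap or an
ambiguity code is excluded from numerator and denominator. This distance
satisfies identity and symmetry but not necessarily the triangle
inequality, and none of the downstream uses require it. Within each taxon
the primary reference S minimizes the median distance to the other
members (ties broken lexicographically); members farther than 0.015 from
S — i.e. below 98.5% identity, a conventional species boundary — are
discarded as probable mislabels. Representatives are then chosen to
maximize the summed pairwise distance of the selected set; the exact
problem is NP-hard, so a greedy forward selection is used, which on
exhaustive 8-choose-5 checks stays within 10% of the optimum. S and any
type strains are always included; the default is five per taxon.

When no externally inferred tree is supplied, a neighbor-joining tree
built from the fraction distances, midpoint-rooted, with negative NJ
branch lengths clamped to zero, stands in. NJ on a desk-scale alignment
recovers the species clades (verified in tests); the interface accepts a
maximum-likelihood tree whenever one is available, and nothing downstream
depends on how the tree was produced.

## Edge labeling and classification

Every edge receives the most specific taxonomic rank at which the leaves
on its **distal** side (the side the edge leads to) carry exactly one
taxid; terminal and within-clade edges therefore get species labels and
clade stems get the species when the clade is one species, the genus when
it subtends several. Proximal-side purity deliberately never labels an
edge: it would label a clade's stem with the *neighboring* clade's
species. The stricter alternate reading — exactly one taxid present on
both sides of the edge — is available behind `strategy="both_sides"`; on
clean monophyletic data the two readings agree on all strictly
within-clade edges (tested).

A placed read is classified at the most specific taxid whose cumulative
posterior — the sum of posteriors on edges labeled with that taxid or any
of its descendants — reaches the cutoff (default 0.9). Cumulative
posteriors are monotone along the lineage and reach 1 at the root, so
every read classifies at some rank. Attachments are renormalized to sum
to one on load, since exported weight ratios are often truncated.
Genus-or-higher calls get a compound name listing up to three descendant
taxa with individual posterior above 0.05, joined with `/`.

The bundled placer (`naive_place`) scores each reference leaf by the best
ungapped sliding-window identity of the read against the degapped
reference, turns the top-k scores into posteriors with a
temperature-controlled softmax (T = 0.02; exact matches take all the
mass), and attaches the read at the midpoint of those leaves' terminal
edges with a 0.01 pendant. It is a simple placer adequate for desk-scale
trees with well-separated clades; external placements arrive via jplace.

## KR distance and squash clustering

The Kantorovich–Rubinstein (earth-mover) distance between two unit mass
maps P, Q on the tree is Z(P,Q) = ∫_T |F(y)| dy with F(y) the net signed
P−Q mass in the subtree below point y. F is piecewise constant along an
edge with breakpoints exactly at the point masses, so one post-order
traversal that accumulates subtree mass and integrates segment by segment
is exact — no discretization anywhere. With all mass on leaves this
reduces to Σ_e len(e)·|A_e − B_e|, the weighted-UniFrac form; both this
identity and agreement with a blind midpoint-rule integration oracle are
asserted in tests, along with the metric axioms on random triples. Only
the exponent p = 1 (the UniFrac-comparable case) is implemented.

Squash clustering is agglomerative with the inter-cluster distance
defined as the KR distance between the clusters' *averaged* ("squashed")
mass maps; merged averages weight each child by its member count, and
each child's branch length is the KR distance from its own average to
the merged average — hence trees are generally not ultrametric, and
duplicated samples form zero-length cherries. Merge ties break on the
lexicographically smallest pair of cluster representatives, so sample
order never changes the result. Bootstrap supports resample each sample's
placements with replacement, rebuild mass maps, re-cluster, and report
for each internal node the fraction of replicates containing its exact
leaf bipartition.

Islands: each read is reduced to its best attachment point; single-linkage
clusters under tree path distance with cutoff 0.02 become islands, kept
only when their reads come from at least two subjects, labeled by the
majority classification, and represented by the read closest to the
attachment-point medoid. Best placements (not the posterior spread) define
membership, matching per-read cluster semantics; a pairwise distance
matrix is built, so inputs are expected at the scale of one order's reads
(hundreds), not a whole run.

## Edge PCA

Sample s maps to a vector x_s over edges with x_s(e) = (mass distal of e)
− (mass proximal of e) = 2·distal − 1; point masses on e itself count as
distal. Covariance (not correlation) PCA is applied to these vectors —
the transform already puts all edges on one scale — with a deterministic
sign convention (largest-magnitude loading positive). Using raw distal
mass instead of the signed difference gives identical eigenvectors and
variance fractions with eigenvalues scaled by 1/4 (asserted in tests);
zero-variance edges are retained, which is harmless under covariance PCA.
Components are projected back onto the tree as `[&weight=...]` edge
annotations that round-trip through the bundled parser.

## Ecology

Shannon diversity uses the natural log (configurable); Chao1 defaults to
the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)) with the classic
f₁²/(2f₂) selectable. Taxa are trimmed to the top ceil(0.30·T) by total
abundance before co-occurrence analysis; the trim report states the
retained read fraction, and samples left without reads are dropped with a
warning. Co-occurrence is the Pearson correlation of log(x + 0.5) across
samples — the 0.5 is a continuity correction for zero counts, which is
why the transform is applied to counts — with zero-variance taxa dropped,
and correlation rows clustered by Euclidean distance and complete
linkage. Community summaries report per-group prevalence (fraction of
samples with ≥ 1 read), read share, the per-sample dominant taxon
(plurality by default, majority selectable; ties flagged and broken
lexicographically), and the minimal top-k taxa covering a target read
share.

## ZINB interaction screen

Counts of one taxon follow a mixture: with probability π a structural
zero, otherwise NB(μᵢ, θ) with log μᵢ = β₀ + β_race + β_BV + β_race×BV.
The zero component is intercept-only — every zero count has the same
probability of being structural — which keeps the model identifiable on
sparse taxa. The likelihood is maximized by L-BFGS-B over (β, log θ,
logit π) from two starts (moment estimates of β and θ; π ∈ {0.1, 0.5}),
relative tolerance 1e−8; internal bounds on log θ and logit π guard
against overflow at degenerate optima. The interaction is tested by
D = 2(ℓ_full − ℓ_reduced) against χ²(1) (one interaction column for
binary race × binary BV), with BH adjustment across taxa. Taxa with too
few nonzero counts, an all-zero race×BV cell, or a non-converged fit are
skipped with an explicit reason. The test contrasts two configured race
levels (default White vs Black); samples of other levels are excluded
from this screen.

Simulation behavior at n = 200 per taxon: the type-I error is consistent
with the nominal 0.05 (0.047 over 1500 independent null fits) and the
p-value distribution is uniform by KS; power at a strong interaction
(γ = 1.6) exceeds 0.95. Power grows monotonically across effect sizes;
this is checked at three levels × 120 simulations with n = 160, sizes
chosen to keep the property test deterministic and fast at desk scale.

## Elastic-net sign models

Each clinical sign y (pH as a real value; binary signs as 0/1; clue cells
as ordinal 0/1/2 — the linear, squared-error objective is used for all,
with a logistic variant available but off by default) is modeled as

(1/2n)‖y − β₀ − Xβ‖² + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²],

where X holds log(count + 0.5) per taxon, standardized internally.
Cyclic coordinate descent solves each λ on a 100-point log-spaced path
(λ_max down to 10⁻³·λ_max) with warm starts; the penalized objective is
asserted non-increasing across sweeps — a property of exact coordinate
minimization that doubles as a solver self-check. λ is chosen by k-fold
cross-validation (folds seeded; stratified on y for binary signs), by CV
minimum by default with the sparser 1-SE rule selectable. Defaults
α = 0.5 and 10 folds are package choices; variable-*selection* behavior
(few false positives, empty models for unrelated signs) holds at the
sparse end of the family (α = 1 with the 1-SE rule), while the default is
aimed at prediction. Coefficients are reported on the original scale; the
cross-criterion table counts, per taxon, how many of the four signs it
associates with.

## The synthetic-data generator

The generator defines the study conditions under which everything above
is exercised; what it does and does not emulate bounds what passing tests
say about real data.

**Reference world.** Sequences evolve by i.i.d. per-site substitution on
a fixed star-of-clades skeleton: each species receives a disjoint set of
signature columns (≥ 1.6% of the alignment, 5% when capacity allows)
where its consensus differs from a shared ancestral sequence, and
within-species copies mutate only non-signature columns under a budget of
0.74% per sequence. This guarantees — by construction, not rejection —
within-species distance < 0.015 and between-species distance > 0.03, the
premises of the curation rules. The taxonomy spans root/order/family/
genus/species and includes provisional taxa (BVAB1/2/3, genogroups, sp.
types). Not emulated: indels, rate heterogeneity, chimeras, homopolymer
errors; distances are the only sequence feature the pipeline consumes.

**Cohort.** Sequencing depth is log-normal with mean 1620 reads per
participant (examples and tests set smaller means for speed) and
CV 0.5 — the per-sample depth variance is not a published quantity, so it
is a configurable default. Non-BV samples draw a dominant Lactobacillus
(crispatus-like or iners-like by default; configurable via
`dominant_taxa`) whose compositional share is Beta(12, 1) floored at
0.55 — the floor, plus exemption of the dominant taxon from
zero-inflation, makes "the most abundant taxon is a Lactobacillus" a
construction guarantee rather than a statistical tendency. The remaining
share spreads over the other taxa as Dirichlet(0.4). That concentration
is a deliberate choice: at much smaller values the background shares are
so heavy-tailed that per-cell mean counts of minor taxa swing by an order
of magnitude between metadata groups, which at some seeds cancels a
planted race×BV interaction inside the near-saturated 2×2 fit; at 0.4
the screen is stable while non-BV communities remain strongly dominated.
BV samples draw log-normal abundances (σ = 0.8) with lactobacilli
penalized (iners least, matching its known persistence under BV) and
latent factors shared within configured sub-groups (loading 1.4), which
induces the block co-occurrence structure. Counts are ZINB around
composition × depth (π = 0.12, θ = 2).

Race effects (main and race×BV interaction) multiply per-taxon *expected
counts* — exactly the log-linear mean model the ZINB regression fits —
rather than perturbing the composition: compositional planting leaks
negative pseudo-interactions into every other taxon through
renormalization, so non-interacting taxa would not be null.

The Nugent score is a logistic function of the log Lactobacillus read
fraction (midpoint at 25%, slope 2.5, ±1 noise, clipped to 0–10), which
reproduces the qualitative continuum of intermediate scores as
Lactobacillus declines. Each Amsel sign is a linear latent in rectified,
depth-centered log counts of its driver taxa plus noise; pH adds its
latent to a 4.1 baseline, clue cells discretize at two cut points into
none/<20%/>20%, and the composite diagnosis applies the ≥ 3-of-4 rule
exactly (pH > 4.5 as the pH criterion). Under the defaults this yields
~88% Amsel positivity in BV-regime samples and ~6% in non-BV samples —
deliberate, realistic discordance rather than a perfect label.

**Placements and FASTQ.** Each simulated read puts 1 − spread of its
posterior on edges inside its source species' clade (split over one or
two edges) and the remainder on random outside edges; per-sample read
totals equal the count matrix row exactly. FASTQ runs are barcode +
primer + mutated reference subsequence (0.4% substitution rate, inserts
210–260 nt) with Gaussian per-base qualities, plus injected failures
(unknown barcode, 80–190 nt inserts, mean-18 qualities) recorded in a
JSON log so QC can be checked against ground truth.

**What passing tests do not show.** The generator has no chimeras, no
alignment errors, no primer bias, no taxon missing from the reference —
so classification accuracy here is an upper bound; real accuracy depends
on reference completeness, which is exactly what iterative curation
addresses. Community realism is structural (dominance, diversity
contrast, sub-groups, interactions), not a fit to any real cohort's
abundance tables.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale as the
package's own defaults: 12-taxon worlds with 3–4 sequences per taxon,
cohorts of 40–400 samples at mean depths of 60–400 reads, 100 bootstrap
replicates, 500-taxon null calibrations at n = 200, and 20-seed selection
experiments. The pipeline demo (60 samples) completes in well under five
minutes on one CPU; `scripts/acceptance.py` takes about a minute.

## Known limitations

* The naive placer is ungapped and identity-based; it is not a substitute
  likelihood engine and will misplace reads on trees with short internal
  edges or heavy rate variation. Use jplace input from a real placer for
  anything beyond well-separated clades.
* Island clustering materializes an all-pairs distance matrix (O(n²)).
* The ZINB zero component is intercept-only by design; data with
  covariate-dependent dropout will push zero-inflation into θ.
* Binary signs use the linear objective by default; coefficients are
  interpretable as associations, not probabilities.
* The KR implementation is exact but per-pair; squash clustering of
  hundreds of samples recomputes averages pairwise and scales roughly
  quadratically in sample count.
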