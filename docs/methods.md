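# Methods

## The network model

`respnet` models a disease-context interactome as an undirected graph over
three node classes — genes, chemicals, diseases — with five admissible edge
classes: gene–gene, gene–chemical, chemical–chemical, disease–gene and
disease–chemical.  Disease–disease links do not exist in the model, and
self-interactions are permitted for genes only (protein self-interactions).
Every edge carries an annotation: a set of curation types from the closed
vocabulary {therapeutic, marker/mechanism, increases, decreases, affects}
plus optional protein-modification tags (ubiquitination, phosphorylation,
oxidation, cleavage, methylation, hydrolysis, hydroxylation, glycosylation,
glucuronidation, acetylation, nitrosation, ribosylation).  Edge polarity is
derived: *positive* when the types are all positive-leaning (therapeutic /
increases), *negative* when all negative-leaning (marker/mechanism /
decreases), *mixed* otherwise — including `affects`, conflicting sets, and
the empty set.  Untyped protein–protein edges therefore report `mixed`; the
positive/negative dichotomy simply does not apply to them.

Node identity is a case-sensitive exact string after whitespace trimming —
no synonym resolution, mirroring a single normalized-name namespace.  A name
used as two different kinds is rejected at load time.

## Construction rules

`filter_to_disease_context` restricts raw tables to a disease list.
Entities with a direct curated disease association (DirectEvidence in
{therapeutic, marker/mechanism, both}; `none` rows are treated as
non-curated inferences and never create links) *anchor* the context.  A
chemical–gene interaction is kept when **either** endpoint is anchored —
this reproduces a construction in which chemical–gene interactions are
batch-collected from both the disease-linked chemicals and the
disease-linked genes — and retained entities are the anchored ones plus the
partners those interactions pull in.  A protein–protein row needs both genes
retained and at least one of the pair anchored.  By construction every
retained gene or chemical is within two steps of a disease.

`dedup_bidirectional` collapses the duplicated query orientations of
chemical–gene rows into one undirected edge per unordered pair, unioning
interaction types; treating all links as bidirectional is justified by the
negligible fraction of genuinely directional curations in such data.

Chemical–chemical edges exist only in the therapeutic network and are
*derived*: when a second chemical from the vocabulary appears in the free
text of a chemical–gene interaction (exact longest match, word-boundary
delimited, case-insensitive), an edge between the two chemicals is emitted
with the host interaction's types.  The whole network has no
chemical–chemical edges.

The therapeutic network keeps chemicals with at least one therapeutic
disease indication (`therapeutic` or `both` — "both" counts as therapeutic
because the criterion is *at least one* therapeutic indication), the genes
linked to a retained chemical (a gene kept only by its disease link is
dropped), all diseases of the whole network, and the derived
chemical–chemical edges.

## Similarity, its statistics, and stability

The Jaccard coefficient of two nodes is intersection over union of their
neighbor sets, where a set contains the node itself iff it self-interacts;
0/0 is defined as 0.  Linked-vs-unlinked comparisons use the one-sided
Mann–Whitney U test (alternative: linked pairs are stochastically more
similar) with the tie-corrected normal approximation — Jaccard distributions
on sparse networks are extremely tie-heavy, so an exact U would be both
intractable and unnecessary at these sample sizes.

Within a sub-network, a pair's percentile rank uses mid-rank tie handling
(fraction of coefficients strictly below plus half the ties, ×100) against
all *other* unordered pairs of the sub-network.  Excluding the query pair
itself makes the conventions coherent: a unique maximum ranks at 100, and an
all-tied sub-network puts every pair at 50 — the middle band.  Bands are
upper25 (≥75), lower25 (≤25), middle (otherwise).

Stability: for each admissible missing edge of a sub-network (non-adjacent,
not disease–disease), the edge is added, all pairwise coefficients are
recomputed, and a two-sided two-sample Kolmogorov–Smirnov test compares the
perturbed and original distributions.  For tiny pooled samples (≤18 values)
the p-value is computed by exhaustive permutation enumeration, which stays
valid under ties — the classical exact KS distribution assumes continuity
and is measurably wrong on, e.g., 3-vs-3 Jaccard samples; below 25 values
per side the classical exact method is used, otherwise the asymptotic
distribution.  Single additions barely move the distribution of larger
sub-networks (mean p ≈ 0.9–1.0 at ≥15 nodes), while small or dense
sub-networks are visibly perturbed — the measure is robust exactly where it
is used.

## Complex detection

The molecular-complex algorithm weights each vertex by *k* · density of the
highest *k*-core of its closed neighborhood (0 below the degree cutoff),
then grows complexes greedily: seeds in descending weight order, BFS
expansion admitting unassigned neighbors with weight ≥ seed weight × (1 −
node score cutoff) up to the depth limit.  Published parameter defaults:
degree cutoff 2, node score cutoff 0.2, k-core 2, max depth 100; haircut on,
fluff off.  Where the classical formulation is order-dependent or silent,
deterministic choices are made: weight ties break lexicographically by node
id; zero-weight vertices never seed; every reached vertex is consumed even
if post-processing later trims it; haircut iteratively removes degree-1
members (reducing the complex to its 2-core); the complex is restricted to
the seed's connected component and dropped if the seed itself was trimmed;
fluff (off by default) admits unassigned neighbors whose
closed-neighborhood density reaches the node score cutoff.  Typed
multi-class edges collapse to simple unweighted edges and self-loops are
ignored for clustering.

A known sensitivity, visible on synthetic data: when intra-block vertex
weights straddle the 80%-of-seed threshold, a dense block can split into two
complexes.  This is inherent to the percentage-of-seed expansion rule, not a
defect of the reimplementation.

## Matrix clustering

The binary interaction matrix has one row/column per node in lexicographic
order, cell 1 iff an edge exists, diagonal 1 iff a self-interaction; nodes
with no interactions are excluded by default (all-zero rows have undefined
similarity).  Row similarity is uncentered correlation — cosine on raw
values without mean-centering, which on binary rows counts shared neighbors
normalized by degree.  Agglomeration is average linkage in similarity space:
cluster–cluster similarity is the unweighted mean of cross-pair
similarities, maintained exactly as cross-pair sums so the mean is exact on
division; the most similar pair merges first, ties breaking
lexicographically on the smallest member node id.  Average linkage admits no
inversions, so merge similarities are non-increasing and a threshold cut is
well-defined: clusters are the maximal subtrees whose internal merges all
reach the threshold, keeping those with ≥2 leaves.

The clustered-node curve (total leaves in ≥2-node clusters per threshold) is
non-increasing; inflection detection smooths it with a 3-point moving
average (grid step 0.05), takes the discrete second difference, and reports
one threshold per maximal same-sign curvature run — the point of largest
curvature magnitude, middle position under ties, which centers a symmetric
smoothing of a sharp knee.  Reproduced cluster counts at fixed thresholds
are expected to match reference runs only within a small tolerance, because
agglomeration tie-breaking is implementation-defined.

## Link inference and validation

Candidate novel links are unlinked, non-disease–disease pairs inside
detected complexes, sampled uniformly without replacement (seeded), each
annotated with its within-sub-network percentile band; a literature-evidence
column is exported empty for manual curation.  Validation against a
reference protein network takes every reference gene–gene edge whose genes
are present in the study network but whose edge is not (self-interactions
excluded from both sides — their similarity is trivially 1), and compares
their coefficients with the background of all unlinked non-self gene–gene
pairs: a one-sided Mann–Whitney U test plus a decile histogram.  Decile
boundaries are the ordinal decile ranks of the background; a value equal to
a boundary falls into the lower bin, so tie groups move whole-sale into the
bin below the boundary — background deciles are therefore near 10% only up
to tie mass, and with many zero-similarity pairs the lowest bin absorbs
them.  Percentiles for validation are ranked against the full-network
background (not per-sub-network), whereas candidate banding is
per-sub-network: the two uses answer different questions.

## The synthetic-data generator

The generator emulates what the analysis needs from curated-database inputs,
at desk scale (defaults: 100 genes, 150 chemicals, 60 diseases — about a
quarter of the published network; the published class ratios set
`therapeutic_fraction` 0.5 ≈ 578/1177 and `cooccurrence_rate` 0.06 ≈
435/7587).  Background edges are per-class Bernoulli draws (gene–gene 0.005,
other classes 0.015) modulated by per-node lognormal propensities (σ = 0.4,
unit median) for hub-dominated degrees; 25% of chemical–gene rows are
emitted twice to exercise orientation deduplication; 2% of genes
self-interact; DirectEvidence values are sampled with the stated therapeutic
fraction.  With propensity heterogeneity the realized density exceeds the
nominal parameter by the factor E[p_i p_j] = e^{σ²}; at σ = 0 the observed
density is exactly Binomial around the nominal value.

Planted clusters are disjoint mixed-kind blocks — by default three blocks of
12 (9 genes, 1–2 chemicals, 1–2 diseases; gene-dominated so nearly every
internal pair is in an admissible class, and sized near the median dense
sub-network the complex detector is expected to find).  Within-block density
is realized as an exact count: (1 − within_density) of the admissible
internal pairs are *removed*, placed degree-balanced so each member carries
an equal share of the holes.  This makes blocks near-regular, which is what
keeps all member weights within the complex detector's 80%-of-seed
threshold; an iid Bernoulli draw at the same density produces irregular
blocks whose weight spread routinely splits them — a property of the
detection rule, not of the generator.  For the same reason background edges
between members of two different blocks are suppressed: the planted truth
must remain identifiable for recovery to be a meaningful benchmark.  Planted
members are guaranteed one disease association so the context filter cannot
delete planted structure.

A `reference_overlap` fraction of planted gene–gene edges (default 0.15,
again degree-balanced; only gene–gene edges can be withheld into a protein
reference network, so heavier withholding depresses gene weights relative to
their block neighbors) is removed from the tables and placed in the
reference network together with an equal number of random unlinked gene
pairs as noise.  Validation experiments that need ≥200 withheld edges use
gene-heavy configurations (e.g. 10 blocks of 18 at mix 0.8/0.1/0.1, overlap
0.3) rather than the defaults.

What the generator does **not** emulate: real nomenclature and synonymy,
curation biases, snapshot mixing between database versions, degree–degree
correlations beyond the propensity product, and literature-support
annotations.  Passing tests demonstrate that the pipeline's machinery is
correct and that its statistical behavior matches expectations under the
stated generative assumptions — not that real curated networks satisfy those
assumptions.

## Numerical and degenerate-input conventions

Empty networks summarize to zero counts and NaN ratios; the characteristic
path length is the mean shortest-path length over connected pairs, computed
on the largest connected component when disconnected (an averaging
convention — the quantity is not otherwise well-defined on disconnected
graphs).  Mean neighbors averages neighbor-set sizes, so a self-loop counts
once toward its node's degree, consistent with the Jaccard neighbor-set
convention.  Sub-network operations always use the induced sub-network only.
Merge-tie tolerance in agglomeration is 10⁻¹⁵ on similarity; curvature below
10⁻⁹ counts as zero in inflection detection.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
generator output.

## Problem sizes used in the test battery

The default test and acceptance runs use the quarter-scale generator
defaults (≈280-node networks), ten generator seeds for the withheld-edge
validation (≈500 validation pairs each), 500 label permutations for the
calibration of the linked/unlinked test, and 40 sampled perturbations per
sub-network for stability — sizes chosen so the full battery completes in
well under a minute while every statistical conclusion is already stable at
the third significant digit.
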