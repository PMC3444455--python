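# Methods

This note records the scientific and numerical choices behind
`crosspath`: the model, its parameters and defaults, what the synthetic
cohorts do and do not emulate, and the design decisions taken where the
method leaves room.

## Pathway activity: the Pathway Connectivity Index

For a tissue with expression matrix X (genes × animals, log10 ratios to
a common reference), each gene is z-scored across animals (sample, n−1,
standard deviation; a zero-variance gene becomes an all-zero row with a
logged warning) and transformed by the centered sigmoid
h = 1/(1+e^(−z)) − ½. Centering matters: an uncentered sigmoid is
strictly positive, so the sign of any pair sum would always be +1 and
the score could never register joint down-regulation. The centered h is
odd, so negating all z-scores negates every PCI (a property the test
suite asserts end to end).

For a pathway with N scored member genes,

    PCI = (1/N) · Σ_{i≤j} sgn(h_i + h_j) · √|h_i| · a_ij · √|h_j|,   a_ii = 1

where a_ij is the probability of functional linkage between genes i and
j in the supplied gene network (0 for unlinked pairs). Each diagonal
term reduces to h_i, so a gene missing from the interaction network
still contributes its own expression — the score uses every gene, and
genes with more and stronger links (hubs) contribute more through their
off-diagonal terms.

Two reconstruction choices are deliberately configurable, because the
pairwise form admits both readings: `include_diagonal` (default True)
and `normalize` ∈ {"size" (1/N, default), "pairs" (1/#terms)}. All
downstream inference is Spearman-based, hence invariant to any strictly
monotone per-row rescaling of the PCI matrix; the choice between these
variants therefore cannot change which edges or relevances are found,
only the absolute scale of the scores. The vectorized implementation is
checked against a naive double loop to 1e−12.

For group-specific networks (e.g. the eight strain × obesity × age
groups of 5 animals), z-scoring is redone within the subset so each
group network is self-contained.

## Coordination network and permutation calibration

Candidate pairs are gated by curation: curated-linked pathways across
every tissue combination (including within a tissue), plus the same
pathway across different tissues (always a candidate — cross-tissue
coherence of one pathway is a signal of inter-tissue communication).
Edges use |Spearman r| with the sign kept as an attribute; a constant
PCI row yields r = 0 with a warning rather than NaN.

The significance threshold is calibrated by permutation: each round
shuffles the gene row labels within each tissue (preserving every
animal's value multiset and each row's z-score profile, destroying the
gene-to-pathway assignment), recomputes every PCI and candidate |r|,
and pools the values into one null across all candidate pairs. A single
pooled null, rather than per-pair nulls, reflects that one global
threshold is wanted; the empirical p uses add-one smoothing,
p(r) = (1 + #{null ≥ |r|}) / (1 + n_null), so p is never exactly 0 and
p(0) = 1. The threshold for a cut is the smallest observed null value
whose p falls below the cut (+∞, with a warning, when the null is too
small to reach the cut; 0 when the cut is ≥ 1). Defaults: n_perm = 1000
(10 000 via configuration for production runs; the test suite calibrates
with 500), p_cut = 0.005.

On 40-animal null cohorts this calibration lands at |r| ≈ 0.44 — the
familiar magnitude for a 0.005-level rank correlation at that sample
size. A practical caveat found during development: with 5-animal groups
the pooled Spearman permutation null cannot reach p < 0.005 at all
(only 5! rank orderings exist, so the smallest attainable two-tail
probability is ≈ 2/120 ≈ 0.017); group-level networks should therefore
use the fixed-threshold mode (`threshold=0.7` in `fit`), which is
provided for exactly this regime.

Permutation-unit choice: genes are shuffled within each tissue, not
globally across tissues — each tissue's matrix is a separate assay, and
within-tissue shuffling preserves tissue-specific value distributions.
Both the shuffling and the trait permutation below derive from a single
seed, so every run is bit-reproducible.

## Trait relevance, linking, refinement

Trait relevance mirrors the network machinery: the null is built by
permuting the trait vector across animals (default 1000 rounds), pooled
over all PCI rows, with the same p < 0.005 default; a fixed-|r| mode is
available. Missing trait values are dropped pairwise; a constant or
all-missing trait yields an empty relevant set with a warning.

Linking classes, computed for every node against the coordination
network: **direct** = relevant to ≥ 2 traits; **path2** = relevant to
some trait and adjacent to a node relevant to a different trait (both
endpoints of such a pair are marked — the rule is symmetric in the pair,
and marking only one endpoint would make the class depend on
enumeration order); **path3** = the union of the neighbors' relevance
covers ≥ 2 distinct traits, whether or not the node itself is relevant.
A node collects every class it satisfies. The implementation is tested
against an exhaustive (node, trait-pair, neighbor) enumeration.

The merged network holds trait nodes, relevant ∪ linking pathway nodes,
coexpression edges restricted to included nodes, and trait→pathway
relevance edges. Refinement is a single pass (an iterate-to-fixed-point
mode exists behind a flag): first drop pathway nodes of total degree
≤ 1, then drop those whose two smallest unweighted distances to trait
nodes, computed on the merged graph including relevance edges, sum to
more than 6 (unreachable = ∞, so a node that can reach only one trait
is dropped). Trait nodes are never removed. Degree-then-distance
ordering follows the rule's natural reading; the refined node set is
always a subset of the input's.

For the trait × tissue distribution table, a linking node's "attached
traits" are its own relevance traits union those of its coexpression
neighbors — the traits that participate in whichever linking rule fired.
The table's margins (row totals, per-tissue totals) and the per-group
mean row of the group-counts table are pure arithmetic over the cells
and are validated exactly against a published study's printed tables.

## Topology analytics

Degree histograms use 10 evenly spaced bins on ln(degree) between the
min and max positive degree (half-open bins, last closed; all-equal
degrees collapse to one bin); reports drop empty bins and add
ln(count). Betweenness is unnormalized Brandes centrality counting each
unordered pair once with endpoints excluded (networkx's accumulation,
verified against brute-force geodesic enumeration). Dense subregions
reimplement the MCODE procedure — vertex weight = highest k-core number
of the closed neighborhood × that core's density; seed-and-grow
admitting neighbors with weight ≥ (1−vwp)·seed; haircut iterated so
surviving clusters have within-cluster degree ≥ 2; defaults vwp = 0.2,
haircut on, fluff off, per the plug-in's published defaults; score =
density × size. Fisher 2×2 tests use the exact hypergeometric tails
(scipy), BH FDR uses statsmodels.

Category representation tests each (category, tissue) cluster against
the universe of all (pathway, tissue) pairs (a "scored-only" universe is
available — the right choice depends on whether unexpressed pathways are
meaningful zeros, which is a property of the input data). Interaction
enhancement contrasts each node's realized degree k_v with its candidate
opportunities O_v against the network totals via
[[k_v, O_v−k_v], [K−k_v, (O−O_v)−(K−k_v)]], one-sided, BH-corrected;
this opportunity-based table is a design decision — it asks "is this
node more connected than its curation alone affords?", which is the
question degree-after-curation-adjustment poses.

## Synthetic cohorts: what they emulate, what they do not

The generator reproduces the statistical skeleton of the target study:
a 2 × 2 × 2 × 5 factorial cohort (40 animals, labels like
`B6-ob-4wk-r1`) profiled in every tissue; log-ratio expression as
i.i.d. Normal(0, noise_sd) baseline; curated pathways with disjoint
cores (optional overlap), five category labels, and Bernoulli curated
links; a gene network denser within pathways than across.

Planted structure drives validation. Each *active group* owns one
latent activity series per animal, Normal(0, activity_sd), added to all
member genes of its pathways in every tissue — the simplest mechanism
that makes member genes, and hence the pathways' PCIs, co-vary within
and across tissues. Traits are linear in the true PCI of chosen
(pathway, tissue) nodes plus Normal(0, noise): since detection is
Spearman-based and thus invariant to monotone links, linearity costs no
generality. In the standard scenario each trait loads on its own
pathway (in its own singleton group) so recovery has an unambiguous
answer key.

Defaults, chosen once as a realistic desk scale: 60 pathways of 10–30
genes, 1200 genes, 3 tissues, 40 animals, link_density 0.05, noise_sd
0.2 (a typical log10-ratio spread), activity_sd 1.0, planted trait
effect 1.0 = 5 × noise_sd. The full 187-pathway × 6-tissue scale is
reachable by parameters. Sub-minute suites use these sizes; the
calibration tests state their own sizes (500 permutations × 5 cohorts;
20 cohorts for recovery).

Not emulated: probe-level microarray artifacts, dye bias, the two-color
reference design beyond "values are log-ratios", gene-gene correlation
that is not pathway-structured, and trait distributions with heavy tails
or floor effects. Passing tests therefore demonstrate that the pipeline
detects the correlation structure it models, at the planted effect
sizes, under Gaussian noise — not that real tissue data meets those
assumptions.

## Known limitations

- The permutation null pools candidate pairs that share PCI rows, so
  null draws are not independent; the binomial calibration band is
  approximate (it holds comfortably in the suite's null experiments).
- With 5-animal groups the permutation route to p < 0.005 is
  unreachable (see above); fixed thresholds are the supported mode.
- A pathway planted with a cross-tissue latent is detected as
  trait-relevant in *every* tissue, by construction of the generator;
  tissue-specific planting would require per-tissue latents, which the
  `GroundTruth` container could express but the standard scenario does
  not use.
- MCODE details beyond the published defaults (e.g. the exact fluff
  pass) follow this package's reading of the procedure; clusters are
  reported with (nodes, edges) counts so any variant can be compared.
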