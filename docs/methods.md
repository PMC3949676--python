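# Methods

This note records the models, algorithms, parameter choices and numerical
conventions implemented in `metaweight`, including the places where the
design was genuinely open and what was decided.

## Super-metabolic graph

Nodes are enzymes with complete four-field EC codes; EC strings with
wildcard or missing fields are rejected at parse/build time.  Two enzymes
are joined by an (undirected, unweighted) edge iff some reaction annotated
with one and some reaction annotated with the other share at least one
compound.  Conventions:

- Substrates and products are pooled per reaction before testing
  intersection; reaction direction and stoichiometry are ignored.
- Only compound ids beginning with `C` count; ids on the cofactor exclusion
  list (currency metabolites such as ATP, NAD(H)) are removed first, since
  they would otherwise connect nearly every enzyme pair.
- Multiple reactions per enzyme use existential semantics (the graph is a
  union over reactions); self-edges are discarded.
- Edges are simple: one shared compound suffices and additional shared
  compounds do not create parallel edges.  (A metabolite-edge multigraph
  would be the alternative reading; node-weight analyses never consult
  edge multiplicity, so the simple graph is sufficient.)

A pathway subgraph restricts both the node set (the pathway's member
enzymes) and the reaction set: only reactions assigned to the pathway can
create edges, so two members sharing a compound solely through an
out-of-pathway reaction are not connected.  Reaction→pathway assignment
comes from an optional `pathways` column in the reaction table; when the
column is absent the fallback rule assigns a reaction to a pathway iff all
its EC annotations are members.

## Stratified genome sampling

Genome clusterings (16S rRNA similarity, e.g. CD-HIT at 0.8) are consumed
as input.  One sampled dataset takes k genomes from one domain, at most
one per cluster: if the domain has exactly k clusters, every cluster
contributes (only the within-cluster choice varies); with more than k, k
clusters are drawn uniformly without replacement first; with fewer, the
draw fails.  Cluster subsets are drawn independently per replicate, so the
same subset may recur.  Defaults: k = 15, 100 replicates per domain (200
datasets).  RNG streams are derived per (domain, replicate) from one master
seed, so earlier datasets are invariant to adding replicates.

`naive_cluster` is a deliberately simple greedy longest-first clusterer
(k-mer identity to the founding representative, k = 8) so the synthetic
pipeline needs no external tool; it is not a reimplementation of CD-HIT
and is only validated on well-separated synthetic similarity structure.

## Node weights

- **Taxonomic**: presence count / dataset size, for every graph enzyme.
- **Isoenzymatic**: mean count of distinct protein ids per genome
  *containing* the enzyme; 0 when absent from every genome.  The
  denominator choice (containing genomes, not all genomes) keeps the value
  interpretable as copies-per-carrier — near 1.0 for typical single-copy
  enzymes — rather than conflating redundancy with presence, which the
  taxonomic weight already measures.  Distinct isoforms are distinct
  protein ids as annotated; no sequence deduplication.
- **Sequence similarity**: one representative protein per containing
  genome, chosen uniformly by an RNG keyed on (seed, dataset, enzyme,
  genome id) — replicable and independent of iteration order or genome
  position — then the mean over all unordered pair similarities.  Missing
  (not 0) for enzymes in fewer than two genomes.

Similarity backend: Smith–Waterman/Gotoh local alignment, BLOSUM62, gap
existence 11 and extension 1 (a gap of length L costs 11 + L), similarity
= identities / alignment columns of the optimal local alignment, clamped
to [0, 1].  Whether a published "similarity" is identity fraction or a
normalised score varies between aligners; the identity-fraction contract
is fixed here and the backend is pluggable (any `(seq_a, seq_b) -> float`,
or `PrecomputedSimilarity` for externally computed pair scores).
Determinism conventions: traceback ties prefer diagonal, then vertical,
then horizontal; the alignment ends at the first maximum in row-major
order; pairs are canonically ordered before aligning so the similarity is
exactly symmetric.  The DP core is numba-compiled; tests verify it against
an independently coded dict-based DP with the same conventions and against
biopython's `PairwiseAligner` optimal score.

Aggregation across replicates is the per-enzyme mean over replicates where
the value is defined, with the defining-replicate count recorded as
support.  Zero and missing are never conflated, in memory or on disk
("NA").

## Correlation and permutation testing

Spearman's rho (average ranks on ties).  The analytic p-value is two-sided:
exact by full rank-permutation enumeration for n ≤ 8, the large-sample t
approximation for n ≥ 9 (enumerating 9! permutations per call buys nothing
at the sizes where the approximation is already accurate).

The permutation test exploits the structure of the problem: both domains
share one topology and only node weights differ, so shuffling one weight
vector over the nodes yields a topology- and distribution-preserving null.
The p-value is one-tailed on the signed statistic — the fraction of m
shuffles whose rho is ≥ the observed value (or ≤, for negative
hypotheses); m defaults to 1,000 (resolution 0.001) and an exhaustive mode
enumerates all n! permutations for n ≤ 8.  No +1 continuity correction is
applied (matching the plain count-ratio definition); the test's empirical
type-I error at α = 0.05 is verified by simulation.

Inclusion rules: intra-domain analyses use enzymes present in ≥ 2 genomes
of the dataset; inter-domain analyses use enzymes with a defined non-zero
mean weight in either domain, imputing 0 on the missing side.  Replicate
handling follows the study design: intra-domain correlations are computed
per sampled dataset and averaged over replicates; the inter-domain
correlation pairs the replicate-mean weight vectors (a per-replicate
pairing would correlate two independent random draws and mostly measure
sampling noise).

## Specific / ubiquitous enzymes and pathway ratios

With high threshold t_high (default 0.667) and low threshold t_low
(default 1 − t_high for [0, 1]-ranged kinds): specific to A iff
mean_A > t_high and mean_B < t_low; ubiquitous iff both exceed t_high;
otherwise neither.  An undefined mean counts as 0.  For the unbounded
isoenzymatic weight both thresholds are explicit configuration; the
defaults set both to 1 (an enzyme averaging more than one isoform per
carrier in one domain and fewer in the other is called specific), which is
one reasonable reading of a single-threshold rule for an unbounded range —
hence both values are exposed rather than asserted.

Pathway ratios are computed over pathways with ≥ 10 non-zero-mean enzymes
in *both* domains (default `min_weighted` = 10); `n_weighted` counts
member enzymes non-zero in either domain and the specific/ubiquitous
ratios are relative to it.  No multiple-testing correction is applied
across pathway rows.

## Node-weighted graph compression

State: supernodes (disjoint member sets, id = smallest member),
superedges with weights in [0, 1] (self-superedges summarise internal
pairs), plus removed-node and operation logs.  The decompressed graph
broadcasts each superedge weight to all member pairs; uncovered pairs have
weight 0.

Distance between original and decompressed graph:

    d = Σ_{removed v} q(v)·c_node
      + Σ_{retained pairs {u,v}} (q(u)+q(v))/2 · |w_orig(u,v) − w_dec(u,v)|

with c_node = 1.  This charges all four compression error types (spurious
edges, lost edges, lost nodes, altered weights), emphasises high-weight
nodes, and — being an L1 metric over pairs on a common node set — obeys
the triangle inequality, so the total error is upper-bounded by the sum of
per-operation increments.  The function sits behind a single seam so an
alternative algebra can be substituted without touching the greedy loop.

Operations:

- **merge(u, v)**: the superedge from the merged node to each neighbour n
  gets the member-count weighted mean (|u|·w(u,n) + |v|·w(v,n)) / (|u|+|v|)
  (absent edges contribute 0), the choice that minimises the pairwise
  distance term between sequential compressed graphs; internal pairs are
  summarised the same way by a pair-count weighted mean self-superedge.
  An edge is kept iff its new weight ≥ 0.5 (below that, representing the
  mostly-absent edge costs more error than the space it saves; the
  threshold is configurable).
- **delete(e)**: remove one superedge.

After either operation, any supernode with no incident superedges is
removed and its members charged as removed nodes.

The greedy driver evaluates every candidate (merges restricted to
supernode pairs within 2 hops — pairs with no common neighbour cannot
merge cheaply, and the restriction bounds the per-iteration cost — plus
all deletions), scores each by Δdistance/Δsize, and executes the cheapest;
ties break on operation name, then lexicographic ids, making runs fully
deterministic.  It stops when cr ≤ target or nothing can shrink the graph
(the achieved ratio is then reported, not an error).  Candidate evaluation
is analytic (closed-form sums over member counts and weight sums), not by
copying state.  Because the operation sequence is independent of the
target, `compress_sweep` takes snapshots at several ratios in one pass.

Binarisation threshold 0.5 (consistent with the keep-rule) converts
decompressed weights back to edges when counting the changed edges `ce` of
a pathway; spurious superedge-induced pairs inside supernodes are counted.
Pathway compression operates on the pathway subgraph with the same node
weights.  Pathway similarity is 1 − (rn + ce)/(|V_P| + |E_P|), floored at
0; pathways are ranked per domain by descending similarity (ties by name)
and the two domains' similarity vectors are compared by Spearman rho.

## Synthetic data

The generator emits every interchange format the pipeline reads, with
known ground truth:

- **Graph**: a random connected topology at a requested density; one
  compound is minted per planted edge and placed in reactions of both
  endpoint enzymes, so the realised compound-sharing graph equals the
  planted one exactly.  Reactions also carry glycan-style ids and listed
  cofactors so the compound filters are genuinely exercised.  3–10
  pathways partition ~70% of the enzymes.
- **Genomes**: presence of enzyme v is Bernoulli with the domain's
  per-enzyme probability; isoform count is 1 + Poisson(iso_rate) given
  presence (so presence and ≥ 1 isoform coincide); each isoform is a
  point-substituted copy of a per-enzyme cross-domain ancestor at the
  domain's divergence rate.  Ancestor lengths default to uniform 120–300
  residues — long enough for stable alignment identity, short enough for
  all-pairs alignment at desk scale; tests use shorter ranges.
  16S-like sequences are near-copies (1% divergence) of per-cluster
  ancestors, so they re-cluster by construction.
- **Scenarios**: `standard_scenario` plants a shared core (p = 0.95 both
  domains, 25% of enzymes), one specific set per domain (0.95 vs 0.05, 15%
  each) and uniform (0.1, 0.6) background, with 15 and 30 clusters of 3
  genomes — mirroring the 15-cluster smaller domain / larger domain
  asymmetry of the study design at desk scale.  Its optional
  conservation-coupled mode draws per-enzyme divergence from (0.02, 0.4)
  and sets iso_rate = 4 × divergence, planting the negative
  conservation/redundancy association used for sign-recovery checks.
  `core_scenario` (120 enzymes, 25% core, uniform (0.05, 0.5) background,
  *no* planted specifics) isolates the conserved-core compression
  question: domain-specific enzymes are excluded from the shared retained
  set by construction and would depress its mean, and retained-set means
  at deep ratios are only smooth when tens of nodes survive, hence the
  larger, specifics-free graph for that experiment.

What the generator does not emulate: real pathway topology, amino-acid
composition and indel processes, horizontal gene transfer, and annotation
error.  Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted structure, not biological conclusions about
real genomes.

## Determinism and problem sizes

Every stochastic stage keys its RNG stream off one master seed (sampling
per (domain, replicate); representative choice per (dataset, enzyme,
genome)); all tabular output is sorted before writing and the pipeline
manifest records per-file SHA-256 checksums, so identical config + inputs
give byte-identical reports.

Default analysis scales in the test-suite and acceptance script: 60-enzyme
(classification) and 120-enzyme (compression) universes, 100 sampled
datasets per domain for presence-based analyses, 5 replicates for
alignment-heavy sequence-similarity weights, m = 200–1,000 permutations,
compression sweeps over cr ∈ {0.8 … 0.1}.  These sizes were chosen as the
smallest at which the planted effects are comfortably resolvable.

## Known limitations

- The super-graph stores simple edges; metabolite-edge multiplicities are
  not modelled.
- The greedy compression optimises an upper bound on the distance; it is
  not globally optimal (verified only to lie between the exhaustive
  optimum and the worst operation sequence on small graphs).
- The internal aligner targets the documented identity-fraction contract;
  it does not reproduce any specific external aligner's scores bit-exactly.
- `naive_cluster` is a testing convenience, not a CD-HIT substitute;
  production clusterings should be supplied as input.
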