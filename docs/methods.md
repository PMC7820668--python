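# Methods

This note documents the models and procedures implemented in
`microsearch`, the parameters that matter, the design choices that were
genuinely open, and the limits of what the synthetic-data tests show.

## Compositional profiles

A sample is a compositional vector: feature id → relative abundance, in
one of three feature spaces (OTU, species, KO). Profiles are normalized
to sum to 1 on load; database matrices are therefore insensitive to the
scale of the input counts. Normalization iterates the division until the
compensated (`math.fsum`) total is exactly 1.0, which makes it idempotent
bit-for-bit — a property the determinism guarantees rely on.

OTU profiles can be corrected for 16S amplicon copy number: each
abundance is divided by its marker-gene copy number (≥ 1) and the profile
renormalized. Features missing from the copy-number table default to 1
with a warning, the usual practice when the catalog is incomplete.

Lineage strings are parsed leniently into a fixed seven-rank frame
(kingdom…species). Empty labels (`f__`), missing trailing ranks, and
unparseable tokens become the explicit `UNCLASSIFIED` sentinel rather
than empty strings, so aggregation buckets are unambiguous.

## Similarity kernel

The phylogeny-weighted similarity of two normalized profiles on a rooted
tree with branch lengths is defined by a bottom-up matching recursion:

1. At each leaf, the overlap `min(aᵢ, bᵢ)` is matched at weight
   `exp(0) = 1`. The residuals `aᵢ − min` and `bᵢ − min` become mass
   packets with accumulated distance 0.
2. Ascending an edge of length ℓ adds ℓ to a packet's accumulated
   distance. Packets from the same profile arriving at a node are pooled
   into one packet whose distance is the mass-weighted mean of the
   merged packets. Pooling per node/side (rather than tracking per-leaf
   provenance) is part of the definition: it bounds the evaluation at
   O(nodes) per pair.
3. At each internal node (the root included), the pooled residuals match
   `m_v = min(R_v^A, R_v^B)` at weight `exp(−(D_v^A + D_v^B))`; the
   matched mass is removed and the remainders continue upward.
4. The similarity is the sum of all weighted matches. Residual mass
   surviving past the root contributes nothing.

Verifiable consequences, all asserted in the tests: the metric is
symmetric, bounded in [0, 1], equals 1 for identical profiles, is ≥ the
plain leaf overlap `Σ min(aᵢ, bᵢ)` (ancestral matches only add), equals 1
exactly when all branch lengths are 0, and converges to the leaf overlap
as branch lengths grow (at lengths ≥ 50 the ancestral weight is
≤ exp(−100)). A two-leaf cherry with unit branches and disjoint unit
masses scores exactly `exp(−2)`.

The kernel is evaluated in a single post-order pass over a flattened tree
(`FlatTree`), vectorized across database samples: all per-node operations
are elementwise over the candidate axis, so scoring one query against m
candidates costs one pass with length-m vector operations per node.
Per-pair scoring is the m = 1 case of the same code path, which is why
indexed search with a full candidate pool reproduces exhaustive search
bit for bit.

Features absent from the reference tree are dropped and the profile
renormalized; the dropped mass is reported as a diagnostic
(`SimilarityResult.dropped_mass_*`), mirroring closed-reference OTU
semantics. A profile entirely disjoint from the tree is an error.

## Taxonomy trees (the dynamic variant)

Species profiles are scored on a taxonomy tree built from the lineages of
exactly the features present in the two profiles. Construction rule: the
internal node chain for a feature consists of its classified rank
prefixes above the deepest one; the leaf itself occupies the deepest
classified rank step. Hence two fully classified congeneric species are
sibling leaves one edge below their genus node; a feature classified
through r ranks sits r edges below the root; a fully unclassified feature
hangs one edge below the root; features with identical full lineages
remain distinct sibling leaves. Unclassified ranks are skipped rather
than materialized as placeholder nodes, so a species unclassified below
its genus still matches congeners at the genus level — the point of
building the tree dynamically.

Every edge has length `edge_length`, default `ln 2 ≈ 0.6931`, chosen so
that under the `exp(−D)` discount each taxonomic rank crossed halves a
match's weight: sibling species score ¼, confamilial species in
different genera 1/16, and two features sharing no rank at all
`2^−14 ≈ 6.1e−5`. The parameter is exposed for users who prefer a
different per-rank discount.

Node identity is the rank-prefix path, so the tree (and the score) is
independent of insertion order, and adding features to the tree does not
change the score of a pair already on it — which lets the database cache
one taxonomy tree over its feature union instead of rebuilding per pair.

## Functional similarity

KO profiles are compared with Bray-Curtis similarity,
`1 − Σ|aᵢ − bᵢ| / Σ(aᵢ + bᵢ)` over the feature union (absent features
count as 0), which for normalized profiles reduces to
`1 − ½ Σ|aᵢ − bᵢ|`. The tests cross-check this against SciPy's
independent Bray-Curtis implementation to 1e−12.

## Two-tier index

Index keys aggregate each profile: taxonomic profiles by family label
(`UNCLASSIFIED` families pool into `f__UNCLASSIFIED`; species databases
use the same family scheme as OTU databases), functional profiles by
BRITE level-2 pathway, a KO mapped to several pathways splitting its
abundance equally (mass-preserving; unmapped KOs pool into `UNMAPPED`).

Candidate selection ranks database samples by Bray-Curtis distance
between key vectors — chosen because it is consistent with the
functional metric and cheap on the short key vectors — and keeps the
nearest `candidate_k = max(candidate_floor, candidate_multiplier ×
max_matches)`, defaults 100 and 10. Only those candidates are scored
exactly. The similarity cutoff (default 0.6) is applied after exact
scoring and before truncation to `max_matches` (default 10). All ties —
in key distance and in similarity — break by sample id ascending, so
results are deterministic. With `candidate_k ≥ n` the candidate set is
the whole database and indexed search equals exhaustive search exactly;
with the defaults it performs at most `candidate_k` full similarity
evaluations instead of n, the hardware-independent measure of the
index's advantage.

Indexes persist as a TSV key matrix plus a JSON manifest carrying the
feature space, key scheme, sizes, and a SHA-256 checksum of the key file;
loading verifies the checksum.

## Curation and metadata

Each sample carries a unified metadata record (project id, habitat
domain/type/details, sampling context, sequencing technology, NSTI for
16S-inferred functional profiles); arbitrary extra columns are preserved
verbatim through load/save. Habitat domains are a fixed three-way
vocabulary; habitat types ship as a configurable 22-category list.

Curation applies three rules in a fixed order (so each excluded sample
gets exactly one reason): `missing_habitat` when domain, type, and
details are all absent; then, for amplicon samples only, `low_reads`
below 500 total reads and `high_unannotated` above 20% unannotatable
reads. Boundaries are strict as stated: 499 reads are excluded and 500
kept; 0.201 is excluded and 0.200 kept. Curation is idempotent on the
retained set.

## Synthetic data

The generator emulates the one structural property search exploits:
habitat-like clusters of compositional profiles. Cluster centroids are
drawn Dirichlet(1) over the feature simplex; each sample is drawn
Dirichlet(concentration × centroid); each cluster is assigned a habitat
type (and a project, so sample ids follow the project-prefix rule).
Defaults: 300 samples, 200 features, 10 clusters, concentration 1000 —
at which within-cluster Bray-Curtis similarity (~0.8) comfortably
exceeds between-cluster similarity (~0.5), a realistic degree of habitat
separation. Queries with a known correct answer are Dirichlet
resamplings of a database sample at strength 200 (a noisy
re-measurement); at that strength the exhaustive rank-1 hit recovers the
source sample in ≥ 95% of 200 queries. OTU fixtures also include a
random bifurcating reference tree (exponential mean-0.5 branch lengths)
and a lineage table drawn from a random but internally consistent
hierarchy (with ~10% species-level and ~3% genus-level unclassified
features); KO fixtures include a random KO→pathway map (1–2 of 10
pathways per KO). All outputs are pure functions of (config, seed) down
to the serialized bytes.

What the generator does **not** emulate: real habitat-specific taxon
distributions, sequencing noise at the read level, sparsity patterns of
real OTU tables (thousands of features, heavy zero-inflation), or
phylogenetic signal linking the reference tree to the abundance
clusters (tree and clusters are independent). Passing tests therefore
demonstrate the engine's correctness and exactness properties — not
field performance on real surveys.

## Problem sizes and numerical choices

The test suite and acceptance script run databases of 100–500 samples
over 200 features — sizes at which every property (including the
20-database indexed-vs-exhaustive equivalence sweep and the 200-query
recall measurement) completes in seconds thanks to the vectorized
kernel, while still exercising the same code paths as larger databases.

Numerical details: normalization tolerance 1e−9; mass-weighted pooling
guards 0/0 with "distance 0 for zero mass" (such packets never
contribute); the pairwise-matrix diagonal is set to 1 by definition;
float serialization uses `repr` (shortest round-trip) so rereading a
fixture reproduces the exact values; index and hit files format
similarity to fixed precision only in the user-facing hits TSV (6
decimals).

## Known limitations

* The phylogeny-weighted kernel is this package's normative definition;
  other phylogeny-aware engines may weight ancestral matches differently,
  so absolute similarity values are comparable only within one metric.
* Key-space pruning is heuristic: a sample can be among the exact top
  matches yet fall outside the candidate pool. The recall tests bound
  this risk on clustered data (≥ 95% rank-1 agreement at defaults) but
  adversarial databases can do worse; `candidate_k` is the safety dial.
* BIOM ingestion and sequence-level input are out of scope: profiles are
  expected to be pre-computed by standard upstream pipelines.
* Whether database profiles should be stored raw or normalized is
  underdetermined by the problem; this package normalizes on load.
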