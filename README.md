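# microsearch

Whole-microbiome similarity search over compositional profiles.

Given a query microbiome — expressed as a relative-abundance profile of
OTUs, species, or KEGG Orthology (KO) gene families — `microsearch` finds
the most similar samples in a profile database. It is aimed at
microbiome researchers who want to place a newly sequenced sample in the
context of existing data: "which known samples does this community most
resemble, and from which habitats do they come?"

## The method

Search runs in two tiers:

1. **Candidate pruning on index keys.** Every database sample is stored
   with a low-dimensional *index key*: its profile aggregated by
   family-level taxa (taxonomic profiles) or by KEGG BRITE level-2
   pathways (functional profiles). The query is aggregated the same way,
   and the `candidate_k = max(100, 10 × max_matches)` samples nearest in
   key space (Bray-Curtis distance on the key vectors) survive.
2. **Exact scoring of candidates.** Each candidate is scored with the
   metric appropriate to the feature space, the hits are filtered at the
   similarity cutoff (default 0.6), sorted, and the top `max_matches`
   (default 10) are reported.

The exact metrics are:

| Feature space | Metric |
|---|---|
| OTU (16S amplicon) | phylogeny-weighted matching on a reference tree |
| species (shotgun WGS) | the same kernel on a taxonomy tree built on the fly from lineages |
| KO (functional) | Bray-Curtis similarity `1 − ½ Σᵢ \|aᵢ − bᵢ\|` |

The phylogeny-weighted kernel matches abundance mass bottom-up over the
tree. At each leaf *i* the overlap `min(aᵢ, bᵢ)` is matched at full
weight. Unmatched residual mass climbs toward the root, accumulating
branch length; residuals meeting at an ancestor are matched with weight
`exp(−(D_A + D_B))`, where `D_A`, `D_B` are the mass-weighted mean
distances the two sides have travelled. The score is the sum of all
weighted matches:

```
S(a, b) = Σ_leaves min(aᵢ, bᵢ) + Σ_nodes m_v · exp(−(D_v^A + D_v^B))
```

It is symmetric, lies in [0, 1], equals 1 for identical profiles, and
interpolates between plain profile overlap (long branches) and 1 (zero
branches). For species profiles the tree is a taxonomy tree with every
edge `ln 2` long, so each rank crossed halves a match's weight — and
because the tree is built from exactly the species present in the two
profiles, species missing from any fixed reference still contribute at
their deepest classified rank.

Databases are curated before indexing: samples without habitat metadata
are excluded, as are amplicon samples with fewer than 500 total reads or
more than 20% unannotatable reads.

## Worked example

Everything below is reproducible offline; the `simulate` command writes a
complete synthetic fixture (profile matrix, metadata, reference tree,
lineage table):

```bash
microsearch simulate --seed 42 --n-samples 120 --n-features 150 --out fixture
microsearch build-index --database fixture/database.tsv --feature-space otu \
    --lineages fixture/lineages.tsv --out fixture/idx
# query.tsv: a noisy re-measurement of database sample P001.S00101
microsearch search --database fixture/database.tsv --index fixture/idx \
    --query query.tsv --feature-space otu --tree fixture/tree.nwk \
    --lineages fixture/lineages.tsv --metadata fixture/metadata.tsv --out hits.tsv
```

`hits.tsv`:

```
rank	sample_id	similarity	habitat_domain	habitat_type
1	P001.S00101	0.799532	human associated	gut
2	P001.S00041	0.741646	human associated	gut
3	P001.S00061	0.740598	human associated	gut
4	P001.S00111	0.737788	human associated	gut
5	P001.S00001	0.736778	human associated	gut
6	P001.S00011	0.736483	human associated	gut
7	P001.S00051	0.733802	human associated	gut
8	P001.S00031	0.733456	human associated	gut
9	P001.S00081	0.730283	human associated	gut
10	P001.S00021	0.726403	human associated	gut
```

The rank-1 hit is the query's source sample (similarity 0.800 — the query
is a Dirichlet-resampled, i.e. noisy, copy, so the self-similarity is
below 1), and the remaining hits are its habitat-cluster mates at
similarity ≈ 0.73–0.74. All ten hits clear the default 0.6 cutoff; a
self-query would return the source at exactly 1.000000. Passing
`--exhaustive` disables the index and scores every database sample; with
`--candidate-k` equal to the database size the two produce byte-identical
hit files.

The same workflow runs as a library — `simulate_database`,
`build_index`, `search`, `search_exhaustive` in `microsearch` — which is
what the test suite and acceptance script use.

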