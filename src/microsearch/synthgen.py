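"""Synthetic fixtures: trees, lineages, KO maps, clustered profile databases.

The generator emulates the structure whole-microbiome search exploits:
habitat-like clusters of compositional profiles on the simplex.  Cluster
centroids are drawn Dirichlet(1) over the feature set; samples within a
cluster are drawn Dirichlet(concentration x centroid), so the concentration
parameter controls within-habitat tightness.  Queries with a known correct
answer are produced by Dirichlet-resampling an existing sample.

Everything is a pure function of (config, seed): the same seed reproduces
byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import TreeNode

from .datastore import (
    DEFAULT_HABITAT_TYPES,
    HABITAT_TYPE_DOMAIN,
    MetadataStore,
    SampleRecord,
)
from .errors import ValidationError
from .profiles import (
    UNCLASSIFIED,
    FeatureSpace,
    Profile,
    TaxonomyLineage,
    normalize,
    write_database_matrix,
    write_ko_map,
    write_lineages,
)
from .phylogeny import write_newick
from .datastore import save_metadata

__all__ = [
    "SimConfig",
    "SyntheticDatabase",
    "simulate_tree",
    "simulate_lineages",
    "simulate_ko_map",
    "simulate_database",
    "perturb_query",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions for a synthetic clustered profile database.

    Defaults describe a desk-scale database: 300 samples over 200 features
    in 10 habitat clusters, with concentration 1000 (tight, realistic
    within-habitat similarity) and query perturbation strength 200 (a noisy
    re-measurement of a known sample).
    """

    n_samples: int = 300
    n_features: int = 200
    n_clusters: int = 10
    dirichlet_concentration: float = 1000.0
    perturbation_strength: float = 200.0
    seed: int = 0
    feature_space: FeatureSpace = FeatureSpace.OTU

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1 or self.n_clusters < 1:
            raise ValidationError("all counts must be >= 1")
        if self.dirichlet_concentration <= 0 or self.perturbation_strength <= 0:
            raise ValidationError("concentration and strength must be > 0")


@dataclass
class SyntheticDatabase:
    """A complete ready-to-index fixture."""

    config: SimConfig
    profiles: dict[str, Profile]
    metadata: MetadataStore
    cluster_assignments: dict[str, int]
    tree: TreeNode | None = None
    lineages: dict[str, TaxonomyLineage] | None = None
    ko_map: dict[str, list[str]] | None = None


def _feature_ids(space: FeatureSpace, n: int) -> list[str]:
    prefix = {FeatureSpace.OTU: "OTU_", FeatureSpace.SPECIES: "SP_", FeatureSpace.KO: "K"}[
        space
    ]
    width = 5 if space is FeatureSpace.KO else 4
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_tree(
    n_leaves: int, seed: int, leaf_names: list[str] | None = None
) -> TreeNode:
    """Random rooted bifurcating tree with exponential(mean 0.5) branch lengths.

    Built by repeatedly splitting a uniformly chosen leaf into a cherry, so
    an n-leaf tree has exactly n - 1 internal nodes.
    """
    if n_leaves < 2:
        raise ValidationError(f"need at least 2 leaves, got {n_leaves}")
    if leaf_names is None:
        leaf_names = [f"L{i:04d}" for i in range(1, n_leaves + 1)]
    if len(leaf_names) != n_leaves:
        raise ValidationError("leaf_names length must equal n_leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.extend([first, second])
    leaves = [first, second]
    for _ in range(n_leaves - 2):
        target = leaves[int(rng.integers(len(leaves)))]
        left, right = TreeNode(), TreeNode()
        target.extend([left, right])
        leaves.remove(target)
        leaves.extend([left, right])
    for name, leaf in zip(leaf_names, leaves):
        leaf.name = name
    root.name = "root"
    for node in root.traverse(include_self=True):
        node.length = 0.0 if node is root else float(rng.exponential(0.5))
    return root


def simulate_lineages(
    feature_ids: list[str], seed: int
) -> dict[str, TaxonomyLineage]:
    """Random but internally consistent Greengenes-style lineages.

    A fixed random taxonomy hierarchy (2 kingdoms .. 48 genera) is drawn,
    each feature picks a genus and inherits its full lineage; the species
    label is feature-specific.  10% of features are species-unclassified
    and 3% are also genus-unclassified, mirroring incomplete annotation.
    """
    rng = np.random.default_rng(seed)
    counts = {"k": 2, "p": 5, "c": 10, "o": 16, "f": 24, "g": 48}
    parent: dict[str, np.ndarray] = {}
    levels = list(counts)
    for upper, lower in zip(levels[:-1], levels[1:]):
        parent[lower] = rng.integers(0, counts[upper], counts[lower])
    lineages: dict[str, TaxonomyLineage] = {}
    for fid in feature_ids:
        g = int(rng.integers(counts["g"]))
        f = int(parent["g"][g])
        o = int(parent["f"][f])
        c = int(parent["o"][o])
        p = int(parent["c"][c])
        k = int(parent["p"][p])
        ranks = [
            f"Kingdom{k}",
            f"Phylum{p}",
            f"Class{c}",
            f"Order{o}",
            f"Family{f}",
            f"Genus{g}",
            fid,
        ]
        u = rng.random()
        if u < 0.03:
            ranks[5] = UNCLASSIFIED
            ranks[6] = UNCLASSIFIED
        elif u < 0.10:
            ranks[6] = UNCLASSIFIED
        lineages[fid] = TaxonomyLineage(tuple(ranks))
    return lineages


def simulate_ko_map(
    ko_ids: list[str], seed: int, n_pathways: int = 10
) -> dict[str, list[str]]:
    """Assign each KO to 1-2 of *n_pathways* synthetic BRITE level-2 pathways."""
    rng = np.random.default_rng(seed)
    pathways = [f"B2_{i:02d}" for i in range(1, n_pathways + 1)]
    ko_map: dict[str, list[str]] = {}
    for ko in ko_ids:
        k = int(rng.integers(1, 3))
        chosen = rng.choice(n_pathways, size=k, replace=False)
        ko_map[ko] = [pathways[i] for i in sorted(chosen)]
    return ko_map


def simulate_database(config: SimConfig) -> SyntheticDatabase:
    """Generate a clustered profile database with metadata and search substrate.

    Each cluster plays the role of a habitat: it gets its own Dirichlet(1)
    centroid and a habitat type from the controlled vocabulary.  OTU
    databases also get a random reference tree and lineages; species
    databases get lineages; KO databases get a KO->pathway map.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(5)
    rng_profiles = np.random.default_rng(children[0])
    ss_tree, ss_lineage, ss_komap = children[1], children[2], children[3]
    rng_meta = np.random.default_rng(children[4])
    fids = _feature_ids(config.feature_space, config.n_features)
    centroids = rng_profiles.dirichlet(
        np.ones(config.n_features), size=config.n_clusters
    )
    profiles: dict[str, Profile] = {}
    assignments: dict[str, int] = {}
    store = MetadataStore()
    types = DEFAULT_HABITAT_TYPES
    for i in range(config.n_samples):
        cluster = i % config.n_clusters
        alpha = config.dirichlet_concentration * centroids[cluster] + 1e-9
        vec = rng_profiles.dirichlet(alpha)
        project_id = f"P{cluster + 1:03d}"
        sample_id = f"{project_id}.S{i + 1:05d}"
        total_reads = int(rng_meta.integers(2_000, 50_000))
        unannotated = float(rng_meta.uniform(0.0, 0.15))
        profiles[sample_id] = normalize(
            Profile(
                feature_space=config.feature_space,
                abundances={
                    fid: float(v) for fid, v in zip(fids, vec) if v > 0.0
                },
                total_reads=total_reads,
                unannotated_fraction=unannotated,
            )
        )
        assignments[sample_id] = cluster
        habitat_type = types[cluster % len(types)]
        is_wgs = config.feature_space is FeatureSpace.SPECIES
        store.add(
            SampleRecord(
                project_id=project_id,
                sample_id=sample_id,
                habitat_domain=HABITAT_TYPE_DOMAIN[habitat_type],
                habitat_type=habitat_type,
                habitat_details=f"synthetic {habitat_type} habitat",
                amplicon_sequence_type=None if is_wgs else "16S V4",
                amplicon_platform=None if is_wgs else "Illumina MiSeq",
                has_wgs=is_wgs,
                wgs_platform="Illumina NovaSeq" if is_wgs else None,
                has_function=config.feature_space is FeatureSpace.KO,
                nsti=(
                    float(rng_meta.uniform(0.03, 0.20))
                    if config.feature_space is FeatureSpace.KO
                    else None
                ),
            )
        )
    db = SyntheticDatabase(
        config=config,
        profiles=profiles,
        metadata=store,
        cluster_assignments=assignments,
    )
    seed_of = lambda s: int(s.generate_state(1)[0] % (2**31))
    if config.feature_space is FeatureSpace.OTU:
        db.tree = simulate_tree(config.n_features, seed_of(ss_tree), leaf_names=fids)
        db.lineages = simulate_lineages(fids, seed_of(ss_lineage))
    elif config.feature_space is FeatureSpace.SPECIES:
        db.lineages = simulate_lineages(fids, seed_of(ss_lineage))
    else:
        db.ko_map = simulate_ko_map(fids, seed_of(ss_komap))
    return db


def perturb_query(profile: Profile, strength: float, seed: int) -> Profile:
    """A noisy re-measurement of *profile*: Dirichlet(strength x profile).

    Large strength means small perturbation; the result is normalized and
    fully determined by the seed.
    """
    if strength <= 0:
        raise ValidationError(f"strength must be > 0, got {strength}")
    rng = np.random.default_rng(seed)
    base = normalize(profile)
    fids = [fid for fid, v in base.abundances.items() if v > 0.0]
    alpha = np.array([base.abundances[fid] for fid in fids]) * strength
    vec = rng.dirichlet(alpha)
    return normalize(
        Profile(
            feature_space=profile.feature_space,
            abundances={fid: float(v) for fid, v in zip(fids, vec) if v > 0.0},
        )
    )


def write_fixture_dir(db: SyntheticDatabase, directory: str | Path) -> list[str]:
    """Write a complete ready-to-index fixture directory; returns filenames."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = ["database.tsv", "metadata.tsv"]
    write_database_matrix(db.profiles, directory / "database.tsv")
    save_metadata(db.metadata, directory / "metadata.tsv")
    if db.tree is not None:
        write_newick(db.tree, directory / "tree.nwk")
        written.append("tree.nwk")
    if db.lineages is not None:
        write_lineages(db.lineages, directory / "lineages.tsv")
        written.append("lineages.tsv")
    if db.ko_map is not None:
        write_ko_map(db.ko_map, directory / "ko_map.tsv")
        written.append("ko_map.tsv")
    return sorted(written)
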