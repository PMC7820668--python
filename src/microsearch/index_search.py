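"""Two-tier index and search.

Tier 1 prunes the database by distance on *index keys* — low-dimensional
aggregations of each sample's profile (family-level taxa for taxonomic
profiles, BRITE level-2 pathways for functional profiles).  Tier 2 scores
only the surviving candidates with the exact whole-microbiome similarity
metric, so a search costs at most ``candidate_k`` full similarity
evaluations instead of one per database sample.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import ValidationError
from .phylogeny import DEFAULT_EDGE_LENGTH, build_taxonomy_tree
from .profiles import (
    UNCLASSIFIED,
    FeatureSpace,
    Profile,
    TaxonomyLineage,
    normalize,
)
from .similarity import FlatTree, _align_to_tree, _kernel

__all__ = [
    "KeyScheme",
    "IndexKey",
    "SearchIndex",
    "SearchHit",
    "Database",
    "UNCLASSIFIED_FAMILY_KEY",
    "UNMAPPED_KEY",
    "DEFAULT_MAX_MATCHES",
    "DEFAULT_MIN_SIMILARITY",
    "DEFAULT_CANDIDATE_FLOOR",
    "DEFAULT_CANDIDATE_MULTIPLIER",
    "make_taxonomic_key",
    "make_functional_key",
    "build_index",
    "select_candidates",
    "search",
    "search_exhaustive",
    "save_index",
    "load_index",
    "write_hits",
]


class KeyScheme(str, Enum):
    FAMILY_LEVEL = "family_level"
    BRITE_LEVEL2 = "brite_level2"


#: Aggregation bucket for features whose family rank is unclassified.
UNCLASSIFIED_FAMILY_KEY = "f__UNCLASSIFIED"
#: Aggregation bucket for KOs missing from the pathway map.
UNMAPPED_KEY = "UNMAPPED"

# Search defaults: at most 10 reported matches, each at similarity >= 0.6.
DEFAULT_MAX_MATCHES = 10
DEFAULT_MIN_SIMILARITY = 0.6
# Candidate-pool rule: candidate_k = max(floor, multiplier * max_matches).
DEFAULT_CANDIDATE_FLOOR = 100
DEFAULT_CANDIDATE_MULTIPLIER = 10


@dataclass(frozen=True)
class IndexKey:
    """A sample's aggregated key vector (tier-1 representation)."""

    values: dict[str, float]
    key_scheme: KeyScheme


@dataclass(frozen=True)
class SearchHit:
    sample_id: str
    similarity: float
    rank: int


@dataclass
class SearchIndex:
    """Tier-1 pruning structure: one aggregated key vector per sample."""

    sample_ids: list[str]
    key_ids: list[str]
    key_matrix: np.ndarray  # shape (n_samples, n_keys)
    feature_space: FeatureSpace
    key_scheme: KeyScheme

    def __post_init__(self) -> None:
        if len(self.sample_ids) != self.key_matrix.shape[0]:
            raise ValidationError("sample_ids and key_matrix rows disagree")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in index")

    def __len__(self) -> int:
        return len(self.sample_ids)


def make_taxonomic_key(
    profile: Profile, lineages: Mapping[str, TaxonomyLineage]
) -> IndexKey:
    """Aggregate a normalized taxonomic profile by family-level taxa.

    Features whose family rank is unclassified (or which lack a lineage)
    pool into the :data:`UNCLASSIFIED_FAMILY_KEY` bucket.
    """
    values: dict[str, float] = {}
    for fid, abund in normalize(profile).abundances.items():
        lineage = lineages.get(fid)
        family = lineage.family if lineage is not None else UNCLASSIFIED
        key = UNCLASSIFIED_FAMILY_KEY if family == UNCLASSIFIED else family
        values[key] = values.get(key, 0.0) + abund
    return IndexKey(values=values, key_scheme=KeyScheme.FAMILY_LEVEL)


def make_functional_key(
    profile: Profile, ko_map: Mapping[str, Sequence[str]]
) -> IndexKey:
    """Aggregate a normalized KO profile by BRITE level-2 pathways.

    A KO mapped to several pathways splits its abundance equally among them
    (mass-preserving); unmapped KOs pool into :data:`UNMAPPED_KEY`.
    """
    values: dict[str, float] = {}
    for ko, abund in normalize(profile).abundances.items():
        pathways = ko_map.get(ko) or ()
        if not pathways:
            values[UNMAPPED_KEY] = values.get(UNMAPPED_KEY, 0.0) + abund
        else:
            share = abund / len(pathways)
            for p in pathways:
                values[p] = values.get(p, 0.0) + share
    return IndexKey(values=values, key_scheme=KeyScheme.BRITE_LEVEL2)


def _profile_key(
    profile: Profile,
    feature_space: FeatureSpace,
    lineages: Mapping[str, TaxonomyLineage] | None,
    ko_map: Mapping[str, Sequence[str]] | None,
) -> IndexKey:
    if feature_space is FeatureSpace.KO:
        if ko_map is None:
            raise ValidationError("functional index keys require a KO->pathway map")
        return make_functional_key(profile, ko_map)
    if lineages is None:
        raise ValidationError("taxonomic index keys require a lineage map")
    return make_taxonomic_key(profile, lineages)


def build_index(
    profiles: Mapping[str, Profile],
    *,
    lineages: Mapping[str, TaxonomyLineage] | None = None,
    ko_map: Mapping[str, Sequence[str]] | None = None,
) -> SearchIndex:
    """Build the tier-1 index: one aggregated key vector per database sample.

    OTU and species databases use the family-level scheme; KO databases use
    BRITE level-2 pathways.  Ordering is deterministic (sample ids and key
    ids sorted ascending).
    """
    if not profiles:
        raise ValidationError("cannot index an empty database")
    spaces = {p.feature_space for p in profiles.values()}
    if len(spaces) != 1:
        raise ValidationError("database mixes feature spaces")
    feature_space = spaces.pop()
    sample_ids = sorted(profiles)
    keys = [
        _profile_key(profiles[sid], feature_space, lineages, ko_map)
        for sid in sample_ids
    ]
    key_ids = sorted({k for key in keys for k in key.values})
    col = {k: j for j, k in enumerate(key_ids)}
    matrix = np.zeros((len(sample_ids), len(key_ids)))
    for i, key in enumerate(keys):
        for k, v in key.values.items():
            matrix[i, col[k]] = v
    return SearchIndex(
        sample_ids=sample_ids,
        key_ids=key_ids,
        key_matrix=matrix,
        feature_space=feature_space,
        key_scheme=keys[0].key_scheme,
    )


def _key_distances(query_key: IndexKey, index: SearchIndex) -> np.ndarray:
    """Bray-Curtis distance between the query key vector and every row."""
    col = {k: j for j, k in enumerate(index.key_ids)}
    q = np.zeros(len(index.key_ids))
    extra = 0.0  # query key mass outside the index's key vocabulary
    for k, v in query_key.values.items():
        j = col.get(k)
        if j is None:
            extra += v
        else:
            q[j] = v
    M = index.key_matrix
    num = np.abs(M - q[None, :]).sum(axis=1) + extra
    den = M.sum(axis=1) + q.sum() + extra
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0.0, num / den, 0.0)


def select_candidates(
    query_key: IndexKey, index: SearchIndex, k: int
) -> list[str]:
    """Tier 1: the k samples with smallest key-space Bray-Curtis distance.

    Ties break by sample_id ascending; ``k >= |index|`` returns everything.
    """
    if query_key.key_scheme is not index.key_scheme:
        raise ValidationError(
            f"key-scheme mismatch: query {query_key.key_scheme.value}, "
            f"index {index.key_scheme.value}"
        )
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    d = _key_distances(query_key, index)
    # sample_ids are sorted ascending, so a stable argsort on distance
    # breaks ties by sample_id ascending.
    order = np.argsort(d, kind="stable")[: min(k, len(index))]
    return [index.sample_ids[i] for i in order]


class Database:
    """A profile database with whatever the exact metric needs attached.

    OTU databases need the reference ``tree``; species databases need
    ``lineages``; KO databases need nothing (``ko_map`` is only used for
    building index keys).  Profiles are normalized on intake.  The instance
    counts full similarity evaluations in ``n_similarity_evaluations`` so
    the pruning behaviour of the two-tier search is observable.
    """

    def __init__(
        self,
        profiles: Mapping[str, Profile],
        *,
        tree: TreeNode | None = None,
        lineages: Mapping[str, TaxonomyLineage] | None = None,
        ko_map: Mapping[str, Sequence[str]] | None = None,
        edge_length: float = DEFAULT_EDGE_LENGTH,
    ) -> None:
        if not profiles:
            raise ValidationError("empty database")
        spaces = {p.feature_space for p in profiles.values()}
        if len(spaces) != 1:
            raise ValidationError("database mixes feature spaces")
        self.feature_space: FeatureSpace = spaces.pop()
        self.sample_ids: list[str] = sorted(profiles)
        self.profiles: dict[str, Profile] = {
            sid: normalize(profiles[sid]) for sid in self.sample_ids
        }
        self.lineages = lineages
        self.ko_map = ko_map
        self.edge_length = edge_length
        self.n_similarity_evaluations = 0
        self._col = {sid: i for i, sid in enumerate(self.sample_ids)}

        self._db_features: list[str] = sorted(
            {fid for p in self.profiles.values() for fid in p.abundances}
        )
        if self.feature_space is FeatureSpace.OTU:
            if tree is None:
                raise ValidationError("an OTU database requires a reference tree")
            self.tree = tree
            self._ftree = FlatTree(tree)
            self._matrix, dropped = self._align_matrix(self._ftree)
            if (dropped > 0).any():
                worst = float(dropped.max())
                warnings.warn(
                    f"{int((dropped > 0).sum())} database sample(s) carry abundance on "
                    f"features absent from the reference tree (max dropped mass "
                    f"{worst:.4f}); that mass was dropped and profiles renormalized",
                    stacklevel=2,
                )
        elif self.feature_space is FeatureSpace.SPECIES:
            if lineages is None:
                raise ValidationError("a species database requires a lineage map")
            self.tree = None
            sub = {
                fid: lineages.get(fid, TaxonomyLineage()) for fid in self._db_features
            }
            self._ftree = FlatTree(
                build_taxonomy_tree(sub, edge_length=edge_length)
            )
            self._matrix, _ = self._align_matrix(self._ftree)
        else:
            self.tree = None
            self._ftree = None
            row = {fid: r for r, fid in enumerate(self._db_features)}
            self._matrix = np.zeros((len(self._db_features), len(self)))
            for j, sid in enumerate(self.sample_ids):
                for fid, v in self.profiles[sid].abundances.items():
                    self._matrix[row[fid], j] = v

    def __len__(self) -> int:
        return len(self.sample_ids)

    def _align_matrix(self, ftree: FlatTree) -> tuple[np.ndarray, np.ndarray]:
        matrix = np.zeros((ftree.n_leaves, len(self)))
        dropped = np.zeros(len(self))
        for j, sid in enumerate(self.sample_ids):
            vec, dm = _align_to_tree(self.profiles[sid], ftree)
            matrix[:, j] = vec
            dropped[j] = dm
        return matrix, dropped

    def batch_similarity(
        self, query: Profile, sample_ids: Sequence[str]
    ) -> np.ndarray:
        """Exact similarity of *query* against the listed samples.

        Every call counts one full similarity evaluation per sample scored.
        """
        if query.feature_space is not self.feature_space:
            raise ValidationError(
                f"feature-space mismatch: query {query.feature_space.value}, "
                f"database {self.feature_space.value}"
            )
        query = normalize(query)
        cols = np.array([self._col[sid] for sid in sample_ids], dtype=np.int64)
        self.n_similarity_evaluations += len(cols)
        if self.feature_space is FeatureSpace.KO:
            return self._batch_braycurtis(query, cols)
        ftree, matrix = self._ftree, self._matrix
        extra = [f for f in query.abundances if f not in ftree.leaf_row]
        if self.feature_space is FeatureSpace.SPECIES and extra:
            # Query brings species unseen in the database: rebuild the
            # taxonomy tree over the union.  Scores over shared features are
            # unchanged because node identity is the rank-prefix path.
            union = self._db_features + sorted(set(extra))
            sub = {
                fid: self.lineages.get(fid, TaxonomyLineage()) for fid in union
            }
            ftree = FlatTree(build_taxonomy_tree(sub, edge_length=self.edge_length))
            matrix = np.zeros((ftree.n_leaves, len(self)))
            rows = [ftree.leaf_row[f] for f in self._ftree.leaf_order]
            matrix[rows, :] = self._matrix
        qvec, _ = _align_to_tree(query, ftree)
        return _kernel(ftree, qvec, matrix[:, cols])

    def _batch_braycurtis(self, query: Profile, cols: np.ndarray) -> np.ndarray:
        row = {fid: r for r, fid in enumerate(self._db_features)}
        q = np.zeros(len(self._db_features))
        extra = 0.0
        for fid, v in query.abundances.items():
            r = row.get(fid)
            if r is None:
                extra += v
            else:
                q[r] = v
        B = self._matrix[:, cols]
        num = np.abs(B - q[:, None]).sum(axis=0) + extra
        den = B.sum(axis=0) + q.sum() + extra
        return 1.0 - num / den

    def query_key(self, query: Profile) -> IndexKey:
        return _profile_key(
            normalize(query), self.feature_space, self.lineages, self.ko_map
        )


def _rank_hits(
    sample_ids: Sequence[str],
    similarities: np.ndarray,
    max_matches: int,
    min_similarity: float,
) -> list[SearchHit]:
    pairs = sorted(
        zip(sample_ids, similarities.tolist()), key=lambda t: (-t[1], t[0])
    )
    hits: list[SearchHit] = []
    for sid, sim in pairs:
        if sim < min_similarity:
            continue
        hits.append(SearchHit(sample_id=sid, similarity=sim, rank=len(hits) + 1))
        if len(hits) >= max_matches:
            break
    return hits


def search(
    query: Profile,
    database: Database,
    index: SearchIndex,
    max_matches: int = DEFAULT_MAX_MATCHES,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    candidate_k: int | None = None,
    candidate_floor: int = DEFAULT_CANDIDATE_FLOOR,
    candidate_multiplier: int = DEFAULT_CANDIDATE_MULTIPLIER,
) -> list[SearchHit]:
    """Two-tier search: key-space candidate pruning, then exact scoring.

    The query's index key is computed exactly as the database keys were;
    the ``candidate_k`` samples nearest in key space (default
    ``max(candidate_floor, candidate_multiplier * max_matches)``) are then
    scored with the exact metric.  Hits at or above *min_similarity* are
    returned sorted by similarity descending (ties by sample_id), truncated
    to *max_matches* and ranked from 1.
    """
    if index.feature_space is not database.feature_space:
        raise ValidationError("index and database feature spaces disagree")
    if set(index.sample_ids) != set(database.sample_ids):
        raise ValidationError("index and database cover different sample sets")
    if candidate_k is None:
        candidate_k = max(candidate_floor, candidate_multiplier * max_matches)
    qkey = database.query_key(query)
    candidates = select_candidates(qkey, index, candidate_k)
    sims = database.batch_similarity(query, candidates)
    return _rank_hits(candidates, sims, max_matches, min_similarity)


def search_exhaustive(
    query: Profile,
    database: Database,
    max_matches: int = DEFAULT_MAX_MATCHES,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> list[SearchHit]:
    """Index-disabled search: exact scoring against every database sample."""
    sims = database.batch_similarity(query, database.sample_ids)
    return _rank_hits(database.sample_ids, sims, max_matches, min_similarity)


# ---------------------------------------------------------------------------
# Index persistence: <name>.keys.tsv + <name>.manifest.json
# ---------------------------------------------------------------------------


def _keys_tsv_text(index: SearchIndex) -> str:
    lines = ["sample_id\t" + "\t".join(index.key_ids)]
    for i, sid in enumerate(index.sample_ids):
        row = "\t".join(repr(float(v)) for v in index.key_matrix[i])
        lines.append(f"{sid}\t{row}")
    return "\n".join(lines) + "\n"


def save_index(index: SearchIndex, prefix: str | Path) -> None:
    """Write ``<prefix>.keys.tsv`` and ``<prefix>.manifest.json``."""
    prefix = Path(prefix)
    keys_text = _keys_tsv_text(index)
    keys_path = prefix.with_suffix(prefix.suffix + ".keys.tsv")
    keys_path.write_text(keys_text, encoding="utf-8")
    manifest = {
        "format_version": 1,
        "feature_space": index.feature_space.value,
        "key_scheme": index.key_scheme.value,
        "n_samples": len(index.sample_ids),
        "n_keys": len(index.key_ids),
        "keys_sha256": hashlib.sha256(keys_text.encode("utf-8")).hexdigest(),
    }
    prefix.with_suffix(prefix.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_index(prefix: str | Path) -> SearchIndex:
    prefix = Path(prefix)
    keys_path = prefix.with_suffix(prefix.suffix + ".keys.tsv")
    manifest_path = prefix.with_suffix(prefix.suffix + ".manifest.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    keys_text = keys_path.read_text(encoding="utf-8")
    digest = hashlib.sha256(keys_text.encode("utf-8")).hexdigest()
    if digest != manifest["keys_sha256"]:
        raise ValidationError(f"{keys_path}: checksum mismatch with manifest")
    lines = keys_text.splitlines()
    key_ids = lines[0].split("\t")[1:]
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for line in lines[1:]:
        fields = line.split("\t")
        sample_ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    return SearchIndex(
        sample_ids=sample_ids,
        key_ids=key_ids,
        key_matrix=np.array(rows) if rows else np.zeros((0, len(key_ids))),
        feature_space=FeatureSpace(manifest["feature_space"]),
        key_scheme=KeyScheme(manifest["key_scheme"]),
    )


def write_hits(
    hits: Sequence[SearchHit],
    path: str | Path,
    *,
    metadata: Mapping[str, object] | None = None,
    include_nsti: bool = False,
) -> None:
    """Write hits as TSV: rank, sample_id, similarity (6 decimals), plus
    habitat columns when a metadata store is attached and an NSTI column
    for 16S-inferred functional databases."""
    header = ["rank", "sample_id", "similarity"]
    if metadata is not None:
        header += ["habitat_domain", "habitat_type"]
        if include_nsti:
            header.append("nsti")
    lines = ["\t".join(header)]
    for hit in hits:
        row = [str(hit.rank), hit.sample_id, f"{hit.similarity:.6f}"]
        if metadata is not None:
            record = metadata.get(hit.sample_id)
            domain = getattr(record, "habitat_domain", None) or ""
            htype = getattr(record, "habitat_type", None) or ""
            row += [domain, htype]
            if include_nsti:
                nsti = getattr(record, "nsti", None)
                row.append("" if nsti is None else f"{nsti:.4f}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
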