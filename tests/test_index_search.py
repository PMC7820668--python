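"""Tier-1 key aggregation, candidate pruning, and two-tier search."""

import numpy as np
import pytest

from microsearch import (
    Database,
    FeatureSpace,
    Profile,
    ValidationError,
    build_index,
    load_index,
    make_functional_key,
    make_taxonomic_key,
    normalize,
    parse_lineage,
    perturb_query,
    save_index,
    search,
    search_exhaustive,
    select_candidates,
)
from microsearch.index_search import (
    UNCLASSIFIED_FAMILY_KEY,
    UNMAPPED_KEY,
    IndexKey,
    KeyScheme,
)

from conftest import make_database


class TestTaxonomicKey:
    LIN = {
        "o1": parse_lineage("k__B;p__F;c__C;o__C;f__Lachnospiraceae;g__;s__"),
        "o2": parse_lineage("k__B;p__F;c__C;o__C;f__Lachnospiraceae;g__X;s__"),
        "o3": parse_lineage("k__B;p__B;c__B;o__B;f__Bacteroidaceae;g__;s__"),
    }

    def test_family_aggregation(self):
        p = normalize(
            Profile(FeatureSpace.OTU, {"o1": 0.6, "o2": 0.1, "o3": 0.3})
        )
        key = make_taxonomic_key(p, self.LIN)
        assert key.values == pytest.approx(
            {"Lachnospiraceae": 0.7, "Bacteroidaceae": 0.3}
        )

    def test_single_feature(self):
        p = normalize(Profile(FeatureSpace.OTU, {"o1": 5.0}))
        key = make_taxonomic_key(p, self.LIN)
        assert key.values == pytest.approx({"Lachnospiraceae": 1.0})

    def test_family_unclassified_pools(self):
        p = normalize(Profile(FeatureSpace.OTU, {"u1": 0.4, "u2": 0.6}))
        key = make_taxonomic_key(p, {"u1": parse_lineage("k__B")})
        assert key.values == pytest.approx({UNCLASSIFIED_FAMILY_KEY: 1.0})


class TestFunctionalKey:
    def test_equal_split_across_pathways(self):
        p = normalize(Profile(FeatureSpace.KO, {"K1": 0.5, "K2": 0.5}))
        key = make_functional_key(p, {"K1": ["P1"], "K2": ["P1", "P2"]})
        assert key.values == pytest.approx({"P1": 0.75, "P2": 0.25})

    def test_bijective_map_relabels(self):
        p = normalize(Profile(FeatureSpace.KO, {"K1": 0.3, "K2": 0.7}))
        key = make_functional_key(p, {"K1": ["PA"], "K2": ["PB"]})
        assert key.values == pytest.approx({"PA": 0.3, "PB": 0.7})

    def test_empty_map_pools_unmapped(self):
        p = normalize(Profile(FeatureSpace.KO, {"K1": 1.0}))
        key = make_functional_key(p, {})
        assert key.values == pytest.approx({UNMAPPED_KEY: 1.0})

    def test_key_mass_preserved(self):
        p = normalize(Profile(FeatureSpace.KO, {"K1": 0.2, "K2": 0.5, "K3": 0.3}))
        key = make_functional_key(p, {"K1": ["P1", "P2"], "K2": ["P3"]})
        assert sum(key.values.values()) == pytest.approx(1.0)


class TestBuildIndex:
    def test_one_key_vector_per_sample(self, otu_db):
        synth, _, index = otu_db
        assert len(index) == len(synth.profiles)
        assert index.key_scheme is KeyScheme.FAMILY_LEVEL
        assert index.sample_ids == sorted(synth.profiles)

    def test_rebuild_is_bit_identical(self, tmp_path, ko_db):
        synth, _, _ = ko_db
        for name in ("a", "b"):
            idx = build_index(synth.profiles, ko_map=synth.ko_map)
            save_index(idx, tmp_path / name)
        assert (tmp_path / "a.keys.tsv").read_bytes() == (
            tmp_path / "b.keys.tsv"
        ).read_bytes()

    def test_mixed_feature_spaces_rejected(self):
        profiles = {
            "S1": normalize(Profile(FeatureSpace.OTU, {"o1": 1.0})),
            "S2": normalize(Profile(FeatureSpace.KO, {"K1": 1.0})),
        }
        with pytest.raises(ValidationError):
            build_index(profiles, lineages={})

    def test_empty_database_rejected(self):
        with pytest.raises(ValidationError):
            build_index({}, lineages={})

    def test_persistence_round_trip(self, tmp_path, species_db):
        _, _, index = species_db
        save_index(index, tmp_path / "idx")
        loaded = load_index(tmp_path / "idx")
        assert loaded.sample_ids == index.sample_ids
        assert loaded.key_ids == index.key_ids
        assert np.array_equal(loaded.key_matrix, index.key_matrix)
        assert loaded.feature_space is index.feature_space


class TestSelectCandidates:
    def _index(self):
        rows = {
            "S1": {"P1": 1.0},
            "S2": {"P1": 0.5, "P2": 0.5},
            "S3": {"P2": 1.0},
        }
        key_ids = ["P1", "P2"]
        matrix = np.array([[rows[s].get(k, 0.0) for k in key_ids] for s in rows])
        from microsearch.index_search import SearchIndex

        return SearchIndex(
            sample_ids=list(rows),
            key_ids=key_ids,
            key_matrix=matrix,
            feature_space=FeatureSpace.KO,
            key_scheme=KeyScheme.BRITE_LEVEL2,
        )

    def test_k_at_least_database_returns_all(self):
        index = self._index()
        key = IndexKey({"P1": 1.0}, KeyScheme.BRITE_LEVEL2)
        assert set(select_candidates(key, index, 10)) == {"S1", "S2", "S3"}

    def test_exact_key_match_is_first(self):
        index = self._index()
        key = IndexKey({"P1": 0.5, "P2": 0.5}, KeyScheme.BRITE_LEVEL2)
        assert select_candidates(key, index, 1) == ["S2"]

    def test_orders_by_key_distance(self):
        index = self._index()
        key = IndexKey({"P1": 1.0}, KeyScheme.BRITE_LEVEL2)
        assert select_candidates(key, index, 2) == ["S1", "S2"]

    def test_scheme_mismatch_rejected(self):
        index = self._index()
        key = IndexKey({"F1": 1.0}, KeyScheme.FAMILY_LEVEL)
        with pytest.raises(ValidationError):
            select_candidates(key, index, 2)


class TestSearch:
    def test_self_query_is_rank_one_with_similarity_one(self, any_db):
        synth, db, index = any_db
        sid = db.sample_ids[3]
        hits = search(db.profiles[sid], db, index)
        assert hits[0].sample_id == sid
        assert hits[0].similarity == pytest.approx(1.0, abs=1e-9)
        assert hits[0].rank == 1

    def test_full_candidate_pool_equals_exhaustive(self, any_db):
        """With candidate_k = n the two-tier search is exact: identical ids,
        similarities, and ranks."""
        synth, db, index = any_db
        for qi, seed in [(0, 101), (11, 102), (25, 103)]:
            query = perturb_query(db.profiles[db.sample_ids[qi]], 200.0, seed=seed)
            indexed = search(query, db, index, candidate_k=len(db))
            exhaustive = search_exhaustive(query, db)
            assert indexed == exhaustive

    def test_pruning_bound_on_similarity_evaluations(self, otu_db):
        synth, db, index = otu_db
        query = perturb_query(db.profiles[db.sample_ids[0]], 200.0, seed=5)
        before = db.n_similarity_evaluations
        search(query, db, index, candidate_k=20)
        assert db.n_similarity_evaluations - before <= 20
        before = db.n_similarity_evaluations
        search_exhaustive(query, db)
        assert db.n_similarity_evaluations - before == len(db)

    def test_candidate_k_monotonicity(self, otu_db):
        """Growing the candidate pool never worsens any returned hit."""
        synth, db, index = otu_db
        query = perturb_query(db.profiles[db.sample_ids[9]], 200.0, seed=77)
        prev = None
        for k in (5, 15, 40, len(db)):
            hits = search(query, db, index, candidate_k=k, min_similarity=0.0)
            if prev is not None:
                for h_small, h_big in zip(prev, hits):
                    assert h_big.similarity >= h_small.similarity - 1e-15
            prev = hits

    def test_min_similarity_above_all_pairs_gives_empty(self, ko_db):
        synth, db, index = ko_db
        query = perturb_query(db.profiles[db.sample_ids[1]], 200.0, seed=8)
        assert search(query, db, index, min_similarity=1.0 + 1e-9) == []

    def test_hits_sorted_consecutively_ranked(self, ko_db):
        synth, db, index = ko_db
        query = perturb_query(db.profiles[db.sample_ids[4]], 50.0, seed=9)
        hits = search(query, db, index, max_matches=50, min_similarity=0.0)
        sims = [h.similarity for h in hits]
        assert sims == sorted(sims, reverse=True)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))

    def test_defaults_cap_hits_and_similarity(self, any_db):
        synth, db, index = any_db
        query = perturb_query(db.profiles[db.sample_ids[2]], 200.0, seed=12)
        hits = search(query, db, index)
        assert len(hits) <= 10
        assert all(h.similarity >= 0.6 for h in hits)

    def test_feature_space_mismatch_rejected(self, otu_db):
        _, db, index = otu_db
        query = normalize(Profile(FeatureSpace.KO, {"K1": 1.0}))
        with pytest.raises(ValidationError):
            search(query, db, index)

    def test_exhaustive_single_sample_database(self):
        profiles = {"S1": normalize(Profile(FeatureSpace.KO, {"K1": 1.0}))}
        db = Database(profiles, ko_map={"K1": ["P1"]})
        hits = search_exhaustive(profiles["S1"], db)
        assert len(hits) == 1
        assert hits[0].similarity == pytest.approx(1.0)

    def test_exhaustive_matches_pairwise_matrix_oracle(self):
        """Hit order equals a sort of the pairwise-similarity-matrix column."""
        from microsearch import pairwise_similarity_matrix

        synth, db, index = make_database("ko", n_samples=10, seed=42)
        ids = db.sample_ids
        profiles = [db.profiles[s] for s in ids]
        M = pairwise_similarity_matrix(profiles)
        query = db.profiles[ids[0]]
        hits = search_exhaustive(query, db, max_matches=10, min_similarity=0.0)
        expected = sorted(
            zip(ids, M[0]), key=lambda t: (-t[1], t[0])
        )
        for hit, (sid, sim) in zip(hits, expected):
            assert hit.sample_id == sid
            assert hit.similarity == pytest.approx(sim, abs=1e-12)

    def test_species_query_with_novel_species(self, species_db):
        """A query species absent from the database still searches cleanly."""
        synth, db, index = species_db
        base = db.profiles[db.sample_ids[0]]
        novel = dict(base.abundances)
        novel["SP_NOVEL"] = 0.05
        query = normalize(Profile(FeatureSpace.SPECIES, novel))
        hits = search(query, db, index, candidate_k=len(db))
        assert hits == search_exhaustive(query, db)
        assert hits[0].sample_id == db.sample_ids[0]
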