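import numpy as np
import pytest

from rxnsearch.encoder import EmbeddingPair
from rxnsearch.featurization import featurize_record
from rxnsearch.pca_compress import ProjectionBasis, fit_basis, project, stack_embeddings
from rxnsearch.reaction_io import ReactionRecord
from rxnsearch.search import (
    EmbeddedDatabase,
    QueryError,
    QuerySpec,
    build_index,
    embed_query,
    filter_by_ranges,
    retrieve_topk,
    search,
)


@pytest.fixture(scope="module")
def indexed(tiny_model_module, records_module):
    model, records = tiny_model_module, records_module
    pairs = [model.embed_record(featurize_record(r)) for r in records]
    basis = fit_basis(stack_embeddings(pairs), evr_threshold=0.99)
    return build_index(records, model, basis), basis


# module-scoped copies of session fixtures (keeps this module self-contained)
@pytest.fixture(scope="module")
def records_module():
    from rxnsearch.synthetic_fixtures import FixtureConfig, generate_reactions

    return generate_reactions(FixtureConfig(n_reactions=40, seed=9))


@pytest.fixture(scope="module")
def tiny_model_module():
    from rxnsearch.encoder import EncoderConfig, init_model

    return init_model(EncoderConfig(gnn_layers=2, gnn_hidden=24, projection_hidden=32, p=16, seed=5))


def fake_db(X, q=None):
    """An EmbeddedDatabase wrapping an explicit matrix (for oracle tests)."""
    n, width = X.shape
    q = width // 2
    records = [
        ReactionRecord(record_id=f"r{i:03d}", product="CC", reactants=["CCBr"])
        for i in range(n)
    ]
    basis = ProjectionBasis(
        V=np.eye(2 * q, q),
        singular_values=np.ones(q),
        explained_variance_ratio=np.full(q, 1.0 / q),
        q=q,
        p=2 * q,
    )
    return EmbeddedDatabase(records=records, X=X, basis=basis, model=None)


class TestQuerySpec:
    def test_needs_product_or_reactants(self):
        with pytest.raises(QueryError):
            QuerySpec()

    def test_bad_range(self):
        with pytest.raises(QueryError):
            QuerySpec(product="CC", attribute_ranges={"yield": (90, 10)})

    def test_bad_mode(self):
        with pytest.raises(QueryError):
            QuerySpec(product="CC", match_mode="fuzzy")


class TestBuildIndex:
    def test_shape(self, indexed, records_module):
        db, basis = indexed
        assert db.X.shape == (len(records_module), 2 * basis.q)

    def test_deterministic_rebuild(self, indexed, records_module, tiny_model_module):
        db, basis = indexed
        db2 = build_index(records_module, tiny_model_module, basis)
        np.testing.assert_array_equal(db.X, db2.X)

    def test_row_matches_manual_composition(self, indexed, records_module, tiny_model_module):
        db, basis = indexed
        record = records_module[7]
        pair = tiny_model_module.embed_record(featurize_record(record))
        manual = np.concatenate([project(pair.z, basis), project(pair.z_hat, basis)])
        np.testing.assert_allclose(db.X[7], manual, atol=1e-10)


class TestEmbedQuery:
    def test_full_query_equals_record_row(self, indexed, records_module, tiny_model_module):
        db, basis = indexed
        record = records_module[3]
        query = QuerySpec(
            product=record.product,
            reactants=list(record.reactants),
            reagents=list(record.reagents) or None,
        )
        x = embed_query(query, tiny_model_module, basis, db)
        np.testing.assert_allclose(x, db.X[3], atol=1e-8)

    def test_product_only_duplicates_halves(self, indexed, tiny_model_module):
        db, basis = indexed
        x = embed_query(QuerySpec(product="CCOC(C)=O"), tiny_model_module, basis, db)
        np.testing.assert_array_equal(x[: basis.q], x[basis.q :])

    def test_reactants_only_duplicates_halves(self, indexed, tiny_model_module):
        db, basis = indexed
        x = embed_query(QuerySpec(reactants=["CCO", "CC(=O)O"]), tiny_model_module, basis, db)
        np.testing.assert_array_equal(x[: basis.q], x[basis.q :])

    def test_substructure_single_anchor(self, indexed, records_module, tiny_model_module):
        db, basis = indexed
        # pick a product unique to one record
        products = [r.product for r in records_module]
        unique = [p for p in products if products.count(p) == 1]
        target = unique[0]
        idx = products.index(target)
        x = embed_query(
            QuerySpec(product=target, match_mode="substructure"),
            tiny_model_module,
            basis,
            db,
        )
        matches = [
            i for i, r in enumerate(records_module)
            if _has_substruct(r.product, target)
        ]
        expected = db.X[matches, : basis.q].mean(axis=0)
        np.testing.assert_allclose(x[: basis.q], expected, atol=1e-10)
        assert idx in matches

    def test_substructure_no_anchor_errors(self, indexed, tiny_model_module):
        db, basis = indexed
        with pytest.raises(QueryError, match="anchor"):
            embed_query(
                QuerySpec(product="[Po]", match_mode="substructure"),
                tiny_model_module,
                basis,
                db,
            )


def _has_substruct(smiles, pattern):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles).HasSubstructMatch(Chem.MolFromSmarts(pattern))


class TestFilterByRanges:
    def _db(self):
        X = np.zeros((3, 4))
        db = fake_db(X)
        db.records[0].attributes = {"yield": 75.0}
        db.records[1].attributes = {"yield": 85.0}
        db.records[2].attributes = {}
        return db

    def test_yield_range_excludes_missing(self):
        db = self._db()
        keep = filter_by_ranges(db, {"yield": (80.0, 100.0)})
        assert keep.tolist() == [1]

    def test_missing_matches_flag(self):
        db = self._db()
        keep = filter_by_ranges(db, {"yield": (80.0, 100.0)}, missing_matches=True)
        assert keep.tolist() == [1, 2]

    def test_empty_ranges_keep_all(self):
        db = self._db()
        assert filter_by_ranges(db, {}).tolist() == [0, 1, 2]

    def test_point_range(self):
        db = self._db()
        assert filter_by_ranges(db, {"yield": (85.0, 85.0)}).tolist() == [1]

    def test_unknown_attribute_warns_and_matches_nothing(self, caplog):
        db = self._db()
        with caplog.at_level("WARNING"):
            keep = filter_by_ranges(db, {"pressure": (0.0, 1.0)})
        assert keep.size == 0
        assert any("pressure" in r.message for r in caplog.records)

    def test_inclusive_bounds(self):
        db = self._db()
        assert filter_by_ranges(db, {"yield": (75.0, 85.0)}).tolist() == [0, 1]


class TestRetrieveTopk:
    def test_exact_vector_first_with_zero_distance(self, rng):
        X = rng.normal(size=(20, 6))
        db = fake_db(X)
        result = retrieve_topk(X[5], db, None, K=3)
        assert result.hits[0][0] == "r005"
        assert result.hits[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_candidates(self, rng):
        X = rng.normal(size=(4, 6))
        result = retrieve_topk(rng.normal(size=6), fake_db(X), None, K=10)
        assert len(result.hits) == 4

    def test_matches_bruteforce_oracle_100(self, rng):
        X = rng.normal(size=(100, 8))
        db = fake_db(X)
        x_star = rng.normal(size=8)
        result = retrieve_topk(x_star, db, None, K=10)
        d = np.sqrt(((X - x_star) ** 2).sum(axis=1))
        oracle_ids = [f"r{i:03d}" for i in np.argsort(d, kind="stable")[:10]]
        assert [h[0] for h in result.hits] == oracle_ids
        oracle_d = np.sort(d)[:10]
        np.testing.assert_array_equal([h[1] for h in result.hits], oracle_d)

    def test_distances_non_decreasing(self, rng):
        X = rng.normal(size=(50, 4))
        result = retrieve_topk(rng.normal(size=4), fake_db(X), None, K=50)
        d = [h[1] for h in result.hits]
        assert all(a <= b for a, b in zip(d, d[1:]))

    def test_tie_broken_by_record_id(self):
        X = np.zeros((5, 4))
        result = retrieve_topk(np.zeros(4), fake_db(X), None, K=5)
        assert [h[0] for h in result.hits] == [f"r{i:03d}" for i in range(5)]

    def test_empty_candidates(self, rng):
        X = rng.normal(size=(5, 4))
        result = retrieve_topk(np.zeros(4), fake_db(X), np.array([], dtype=np.int64), K=3)
        assert result.hits == []

    def test_filter_then_retrieve_commutes(self, rng):
        X = rng.normal(size=(30, 6))
        db = fake_db(X)
        for i in range(30):
            db.records[i].attributes = {"yield": float(i)}
        candidates = filter_by_ranges(db, {"yield": (10.0, 20.0)})
        full = retrieve_topk(np.zeros(6), db, candidates, K=5)
        sub_db = fake_db(X[candidates])
        for new_i, old_i in enumerate(candidates):
            sub_db.records[new_i].record_id = db.records[old_i].record_id
        sub = retrieve_topk(np.zeros(6), sub_db, None, K=5)
        assert [h[0] for h in full.hits] == [h[0] for h in sub.hits]
        np.testing.assert_allclose(
            [h[1] for h in full.hits], [h[1] for h in sub.hits]
        )


class TestEndToEnd:
    def test_search_returns_self_first(self, indexed, records_module):
        db, _ = indexed
        record = records_module[11]
        query = QuerySpec(
            product=record.product,
            reactants=list(record.reactants),
            reagents=list(record.reagents) or None,
            K=5,
        )
        result = search(query, db)
        assert result.hits[0][0] == record.record_id

    def test_reproducible_bit_exact(self, indexed):
        db, _ = indexed
        query = QuerySpec(product="CCOC(C)=O", K=7)
        a, b = search(query, db), search(query, db)
        assert a.hits == b.hits

    def test_strict_exact_filters_roles(self, indexed, records_module):
        db, _ = indexed
        record = records_module[2]
        query = QuerySpec(product=record.product, match_mode="exact", K=30)
        result = search(query, db, strict_exact=True)
        assert all(
            next(r for r in records_module if r.record_id == rid).product == record.product
            for rid, _ in result.hits
        )

    def test_range_restricts_hits(self, indexed, records_module):
        db, _ = indexed
        with_yield = [r for r in records_module if "yield" in r.attributes]
        lo = min(r.attributes["yield"] for r in with_yield)
        query = QuerySpec(product=records_module[0].product, attribute_ranges={"yield": (lo, lo)}, K=30)
        result = search(query, db)
        hit_ids = {h[0] for h in result.hits}
        allowed = {r.record_id for r in with_yield if r.attributes["yield"] == lo}
        assert hit_ids <= allowed
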