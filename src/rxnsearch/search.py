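"""Embedded-database construction and top-K retrieval.

Each record is stored as the concatenation x_i = [z'_i || z_hat'_i] of its
reduced target and prediction vectors. A query embeds into the same space;
when one side (product or reactants) is absent the other side is used for
both halves. Substructure queries anchor on database records containing the
pattern and average their stored vectors. Candidates can be pre-filtered by
inclusive attribute ranges; retrieval is an ascending sort of Euclidean
distances with record-id tie-breaking for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .encoder import ReactionEncoder
from .featurization import featurize_molecule_set, featurize_record
from .pca_compress import ProjectionBasis, project
from .reaction_io import (
    ReactionRecord,
    canonicalize_smiles,
    read_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QuerySpec",
    "EmbeddedDatabase",
    "SearchResult",
    "build_index",
    "embed_query",
    "filter_by_ranges",
    "retrieve_topk",
    "search",
]


class QueryError(ValueError):
    pass


@dataclass
class QuerySpec:
    """A search query over any subset of {product, reactants, reagents}."""

    product: str | None = None
    reactants: list[str] | None = None
    reagents: list[str] | None = None
    match_mode: str = "similarity"  # exact | similarity | substructure
    attribute_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    K: int = 30

    def __post_init__(self):
        if self.product is None and not self.reactants:
            raise QueryError("at least one of product or reactants must be provided")
        if self.match_mode not in {"exact", "similarity", "substructure"}:
            raise QueryError(f"unknown match mode {self.match_mode!r}")
        for key, (lo, hi) in self.attribute_ranges.items():
            if lo > hi:
                raise QueryError(f"range for {key!r} has lo > hi")
        if self.K < 1:
            raise QueryError("K must be at least 1")


@dataclass
class EmbeddedDatabase:
    records: list[ReactionRecord]
    X: np.ndarray  # N x 2q
    basis: ProjectionBasis
    model: ReactionEncoder

    def __post_init__(self):
        if self.X.shape[0] != len(self.records):
            raise ValueError("X rows must align with records")
        if self.X.shape[1] != 2 * self.basis.q:
            raise ValueError("X must have 2q columns")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "embeddings.npz", X=self.X)
        write_dataset(self.records, path / "records.jsonl")
        self.basis.save(path / "basis.npz")
        self.model.save(path / "model.npz")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddedDatabase":
        path = Path(path)
        with np.load(path / "embeddings.npz") as arch:
            X = arch["X"]
        return cls(
            records=read_dataset(path / "records.jsonl"),
            X=X,
            basis=ProjectionBasis.load(path / "basis.npz"),
            model=ReactionEncoder.load(path / "model.npz"),
        )


@dataclass
class SearchResult:
    query: QuerySpec
    hits: list[tuple[str, float]]  # (record_id, distance), ascending distance
    K: int


def build_index(
    records: Sequence[ReactionRecord],
    model: ReactionEncoder,
    basis: ProjectionBasis,
    batch_size: int = 256,
) -> EmbeddedDatabase:
    """Embed, project and concatenate every record into the search matrix."""
    records = list(records)
    rows = []
    for start in range(0, len(records), batch_size):
        chunk = [featurize_record(r) for r in records[start : start + batch_size]]
        z, z_hat = model.embed_tuples(chunk, training=False)
        rows.append(
            np.hstack([project(z.data, basis), project(z_hat.data, basis)])
        )
    X = np.vstack(rows) if rows else np.zeros((0, 2 * basis.q))
    return EmbeddedDatabase(records=records, X=X, basis=basis, model=model)


def _substructure_anchors(
    db: EmbeddedDatabase, patterns: Sequence[str], role: str
) -> np.ndarray:
    """Indices of records whose given role contains every pattern."""
    mols = [Chem.MolFromSmarts(p) for p in patterns]
    if any(m is None for m in mols):
        bad = patterns[[m is None for m in mols].index(True)]
        raise QueryError(f"unparsable substructure pattern {bad!r}")
    hits = []
    for i, record in enumerate(db.records):
        targets = [record.product] if role == "product" else record.reactants
        target_mols = [Chem.MolFromSmiles(s) for s in targets]
        if all(
            any(t is not None and t.HasSubstructMatch(pat) for t in target_mols)
            for pat in mols
        ):
            hits.append(i)
    return np.asarray(hits, dtype=np.int64)


def _embed_side_direct(
    molecules: Sequence[str],
    head: str,
    model: ReactionEncoder,
    basis: ProjectionBasis,
    reagents: Sequence[str] | None = None,
) -> np.ndarray:
    graph = featurize_molecule_set(molecules)
    enc = model.encode(graph)
    from .nn import Tensor

    if head == "product":
        vec = model.head_p(Tensor(enc.reshape(1, -1))).data[0]
    else:
        vec = model.head_r(Tensor(enc.reshape(1, -1))).data[0]
        if reagents:
            reagent_enc = model.encode(featurize_molecule_set(list(reagents)))
            vec = vec + model.head_a(Tensor(reagent_enc.reshape(1, -1))).data[0]
    return project(vec, basis)


def embed_query(
    query: QuerySpec,
    model: ReactionEncoder,
    basis: ProjectionBasis,
    db: EmbeddedDatabase | None = None,
) -> np.ndarray:
    """Compute the query vector x* in R^{2q}.

    Exact/similarity queries embed the given molecules through the model.
    Substructure queries average the stored vectors of database records
    containing the pattern(s) on the corresponding role. A missing side is
    substituted by the present one, i.e. [z'||z'] or [z_hat'||z_hat'].
    """
    q = basis.q
    z_side: np.ndarray | None = None
    zhat_side: np.ndarray | None = None
    if query.match_mode == "substructure":
        if db is None:
            raise QueryError("substructure queries need a database to anchor on")
        if query.product is not None:
            idx = _substructure_anchors(db, [query.product], "product")
            if idx.size == 0:
                raise QueryError("no anchor records match the product pattern")
            z_side = db.X[idx, :q].mean(axis=0)
        if query.reactants:
            idx = _substructure_anchors(db, query.reactants, "reactants")
            if idx.size == 0:
                raise QueryError("no anchor records match the reactant pattern(s)")
            zhat_side = db.X[idx, q:].mean(axis=0)
    else:
        if query.product is not None:
            z_side = _embed_side_direct([query.product], "product", model, basis)
        if query.reactants:
            zhat_side = _embed_side_direct(
                query.reactants, "reactants", model, basis, reagents=query.reagents
            )
    if z_side is None:
        z_side = zhat_side
    if zhat_side is None:
        zhat_side = z_side
    return np.concatenate([z_side, zhat_side])


def filter_by_ranges(
    db: EmbeddedDatabase,
    attribute_ranges: dict[str, tuple[float, float]],
    missing_matches: bool = False,
) -> np.ndarray:
    """Candidate indices whose attributes all lie in the inclusive ranges.

    A record lacking a constrained attribute is excluded by default
    (``missing_matches`` inverts that). An attribute key unknown to every
    record logs a warning and simply matches nothing.
    """
    if attribute_ranges:
        known = {k for r in db.records for k in r.attributes}
        for key in attribute_ranges:
            if key not in known:
                logger.warning("attribute %r not present on any record", key)
    keep = []
    for i, record in enumerate(db.records):
        ok = True
        for key, (lo, hi) in attribute_ranges.items():
            if key not in record.attributes:
                ok = missing_matches
            else:
                ok = lo <= record.attributes[key] <= hi
            if not ok:
                break
        if ok:
            keep.append(i)
    return np.asarray(keep, dtype=np.int64)


def retrieve_topk(
    x_star: np.ndarray,
    db: EmbeddedDatabase,
    candidates: np.ndarray | None = None,
    K: int = 30,
    query: QuerySpec | None = None,
) -> SearchResult:
    """Top-K candidates by ascending Euclidean distance to the query vector.

    Ties are broken lexicographically on record_id so results are
    deterministic; an empty candidate set yields an empty result.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if candidates is None:
        candidates = np.arange(len(db.records))
    if candidates.size == 0:
        return SearchResult(query=query, hits=[], K=K)
    dists = np.linalg.norm(db.X[candidates] - np.asarray(x_star), axis=1)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (dists[i], db.records[candidates[i]].record_id),
    )[:K]
    hits = [
        (db.records[candidates[i]].record_id, float(dists[i])) for i in order
    ]
    return SearchResult(query=query, hits=hits, K=K)


def _strict_exact_filter(result: SearchResult, db: EmbeddedDatabase) -> SearchResult:
    by_id = {r.record_id: r for r in db.records}
    query = result.query
    want_product = (
        canonicalize_smiles(query.product) if query.product is not None else None
    )
    want_reactants = (
        sorted(canonicalize_smiles(s) for s in query.reactants)
        if query.reactants
        else None
    )
    kept = []
    for record_id, dist in result.hits:
        record = by_id[record_id]
        if want_product is not None and record.product != want_product:
            continue
        if want_reactants is not None and sorted(record.reactants) != want_reactants:
            continue
        kept.append((record_id, dist))
    return SearchResult(query=query, hits=kept, K=result.K)


def search(query: QuerySpec, db: EmbeddedDatabase, strict_exact: bool = False) -> SearchResult:
    """Full pipeline: embed query, range-filter, retrieve top-K."""
    x_star = embed_query(query, db.model, db.basis, db)
    candidates = filter_by_ranges(db, query.attribute_ranges)
    result = retrieve_topk(x_star, db, candidates, query.K, query=query)
    if query.match_mode == "exact" and strict_exact:
        result = _strict_exact_filter(result, db)
    return result
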