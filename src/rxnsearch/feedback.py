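"""Human-in-the-loop model updating from binary relevance ratings.

Rated search results feed a margin ranking loss: for every ordered pair of
hits whose ratings differ, the better-rated record must sit closer to the
query by a margin. Fine-tuning minimizes the blended objective
``J + lambda * mean ranking loss`` with momentum SGD while batch
normalization stays in evaluation mode (frozen statistics). Distances are
computed in the reduced concatenated space with the projection basis held
fixed, so gradients flow through the model only; afterwards the database
embeddings are refreshed with the updated model under the same basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoder import ReactionEncoder
from .featurization import featurize_molecule_set, featurize_record
from .nn import SGD, Tensor, concat, gather_rows
from .contrastive_trainer import contrastive_loss_tensor
from .pca_compress import ProjectionBasis
from .reaction_io import ReactionRecord
from .search import EmbeddedDatabase, QuerySpec, SearchResult, build_index

logger = logging.getLogger(__name__)

__all__ = [
    "RatingVector",
    "FeedbackConfig",
    "FeedbackEntry",
    "QueryFeedbackSet",
    "margin_ranking_loss",
    "combined_objective",
    "finetune",
    "refresh_index",
]


@dataclass
class RatingVector:
    ratings: list[int]

    def __post_init__(self):
        if any(r not in (-1, 0, 1) for r in self.ratings):
            raise ValueError("ratings must lie in {-1, 0, +1}")


@dataclass
class FeedbackConfig:
    delta: float = 100.0
    lam: float = 0.01
    iterations: int = 100
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-8
    minibatch_size: int = 4096
    tau: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0 or self.lam < 0:
            raise ValueError("delta and lambda must be non-negative")
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")


@dataclass
class FeedbackEntry:
    query: QuerySpec
    result: SearchResult
    ratings: RatingVector

    def __post_init__(self):
        if len(self.ratings.ratings) != len(self.result.hits):
            raise ValueError("ratings must align with search hits")


@dataclass
class QueryFeedbackSet:
    entries: list[FeedbackEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def extend(self, entries: Sequence[FeedbackEntry]) -> None:
        self.entries.extend(entries)


def margin_ranking_loss(
    x_star: np.ndarray,
    hit_vectors: np.ndarray,
    ratings: Sequence[int],
    delta: float,
) -> float:
    """Margin ranking loss over all hit pairs, normalized by 2/(K(K-1)).

    Pairs with equal ratings contribute nothing; for unequal ratings the
    hinge activates unless the better-rated hit is closer by 2*delta (the
    rating gap of 2 scales both the distance term and the margin).
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    k = len(ratings)
    if k < 2:
        logger.warning("margin ranking loss needs at least 2 rated hits; returning 0")
        return 0.0
    d = np.linalg.norm(np.asarray(hit_vectors) - np.asarray(x_star), axis=1)
    ii, jj = np.triu_indices(k, k=1)
    rdiff = ratings[ii] - ratings[jj]
    terms = np.maximum(0.0, rdiff * (d[ii] - d[jj]) + np.abs(rdiff) * delta)
    return float(2.0 / (k * (k - 1)) * terms.sum())


# --------------------------------------------------------------------------
# differentiable path: recompute query and hit embeddings from the live model
# --------------------------------------------------------------------------


class _FeedbackGraphs:
    """Featurized graphs for everything a feedback set needs, cached once.

    Hit records (and substructure anchor records) are pinned by record_id;
    their embeddings are recomputed from the current model each iteration so
    the ranking loss always reflects live parameters.
    """

    def __init__(
        self,
        feedback: QueryFeedbackSet,
        records_by_id: dict[str, ReactionRecord],
        db: EmbeddedDatabase | None,
    ):
        needed: list[str] = []
        self.anchor_ids: list[tuple[list[str] | None, list[str] | None]] = []
        for entry in feedback.entries:
            for record_id, _ in entry.result.hits:
                if record_id not in needed:
                    needed.append(record_id)
            prod_anchor = react_anchor = None
            if entry.query.match_mode == "substructure":
                if db is None:
                    raise ValueError("substructure feedback needs the database")
                from .search import _substructure_anchors

                if entry.query.product is not None:
                    idx = _substructure_anchors(db, [entry.query.product], "product")
                    prod_anchor = [db.records[i].record_id for i in idx]
                    needed.extend(r for r in prod_anchor if r not in needed)
                if entry.query.reactants:
                    idx = _substructure_anchors(
                        db, entry.query.reactants, "reactants"
                    )
                    react_anchor = [db.records[i].record_id for i in idx]
                    needed.extend(r for r in react_anchor if r not in needed)
            self.anchor_ids.append((prod_anchor, react_anchor))
        self.record_ids = needed
        self.row_of = {rid: i for i, rid in enumerate(needed)}
        self.tuples = [featurize_record(records_by_id[rid]) for rid in needed]
        # direct query-side graphs for exact/similarity queries
        self.query_graphs = []
        for entry in feedback.entries:
            product_graph = reactant_graph = reagent_graph = None
            if entry.query.match_mode != "substructure":
                if entry.query.product is not None:
                    product_graph = featurize_molecule_set([entry.query.product])
                if entry.query.reactants:
                    reactant_graph = featurize_molecule_set(entry.query.reactants)
                    if entry.query.reagents:
                        reagent_graph = featurize_molecule_set(entry.query.reagents)
            self.query_graphs.append((product_graph, reactant_graph, reagent_graph))


def _ranking_loss_tensor(
    model: ReactionEncoder,
    basis: ProjectionBasis,
    feedback: QueryFeedbackSet,
    graphs: _FeedbackGraphs,
    delta: float,
) -> Tensor:
    from .encoder import GraphBatch

    V = Tensor(basis.V)
    z, z_hat = model.embed_tuples(graphs.tuples, training=False)
    zp, zhp = z @ V, z_hat @ V
    X = concat([zp, zhp], axis=1)  # rows follow graphs.record_ids
    total = Tensor(0.0)
    for entry, (prod_anchor, react_anchor), (pg, rg, ag) in zip(
        feedback.entries, graphs.anchor_ids, graphs.query_graphs
    ):
        k = len(entry.result.hits)
        if k < 2:
            continue
        rows = np.array([graphs.row_of[rid] for rid, _ in entry.result.hits])
        x_hits = gather_rows(X, rows)
        # query sides in reduced space
        z_side = zhat_side = None
        if entry.query.match_mode == "substructure":
            if prod_anchor:
                anchor_rows = np.array([graphs.row_of[r] for r in prod_anchor])
                z_side = gather_rows(zp, anchor_rows).mean(axis=0)
            if react_anchor:
                anchor_rows = np.array([graphs.row_of[r] for r in react_anchor])
                zhat_side = gather_rows(zhp, anchor_rows).mean(axis=0)
        else:
            if pg is not None:
                enc = model.encode_batch(GraphBatch.from_graphs([pg]))
                z_side = (model.head_p(enc) @ V).reshape(-1)
            if rg is not None:
                enc = model.encode_batch(GraphBatch.from_graphs([rg]))
                side = model.head_r(enc)
                if ag is not None:
                    side = side + model.head_a(
                        model.encode_batch(GraphBatch.from_graphs([ag]))
                    )
                zhat_side = (side @ V).reshape(-1)
        if z_side is None:
            z_side = zhat_side
        if zhat_side is None:
            zhat_side = z_side
        x_star = concat([z_side, zhat_side], axis=0).reshape(1, -1)
        diff = x_hits - x_star
        d = ((diff * diff).sum(axis=1) + 1e-12).sqrt()
        ratings = np.asarray(entry.ratings.ratings, dtype=np.float64)
        ii, jj = np.triu_indices(k, k=1)
        rdiff = ratings[ii] - ratings[jj]
        active = rdiff != 0  # equal-rating pairs contribute exactly zero
        if not active.any():
            continue
        ii, jj, rdiff = ii[active], jj[active], rdiff[active]
        hinge = (
            (gather_rows(d, ii) - gather_rows(d, jj)) * Tensor(rdiff)
            + Tensor(np.abs(rdiff) * delta)
        ).relu()
        total = total + hinge.sum() * (2.0 / (k * (k - 1)))
    return total * (1.0 / max(len(feedback.entries), 1))


def combined_objective(
    minibatch: Sequence[ReactionRecord],
    feedback: QueryFeedbackSet,
    lam: float,
    model: ReactionEncoder,
    basis: ProjectionBasis,
    db: EmbeddedDatabase | None = None,
    tau: float = 100.0,
    delta: float = 100.0,
    _graphs: _FeedbackGraphs | None = None,
) -> Tensor:
    """Blended objective J + lambda * mean ranking loss (differentiable)."""
    if not feedback.entries:
        raise ValueError("feedback set must be non-empty")
    tuples = [featurize_record(r) for r in minibatch]
    z, z_hat = model.embed_tuples(tuples, training=False)
    objective = contrastive_loss_tensor(z, z_hat, tau)
    if lam > 0:
        if _graphs is None:
            records_by_id = {r.record_id: r for r in minibatch}
            if db is not None:
                records_by_id.update({r.record_id: r for r in db.records})
            _graphs = _FeedbackGraphs(feedback, records_by_id, db)
        objective = objective + lam * _ranking_loss_tensor(
            model, basis, feedback, _graphs, delta
        )
    return objective


def finetune(
    model: ReactionEncoder,
    dataset: Sequence[ReactionRecord],
    feedback: QueryFeedbackSet,
    config: FeedbackConfig,
    basis: ProjectionBasis,
    db: EmbeddedDatabase | None = None,
) -> ReactionEncoder:
    """Fine-tune the model on the blended objective with momentum SGD.

    Runs ``config.iterations`` steps; each samples a fresh contrastive
    minibatch from the training dataset. All normalization layers keep
    their frozen statistics throughout. The input model is not mutated.
    """
    if not feedback.entries:
        raise ValueError("feedback set must be non-empty")
    model = model.copy()
    records_by_id = {r.record_id: r for r in dataset}
    if db is not None:
        records_by_id.update({r.record_id: r for r in db.records})
    graphs = _FeedbackGraphs(feedback, records_by_id, db)
    dataset_tuples = [featurize_record(r) for r in dataset]
    m = min(config.minibatch_size, len(dataset))
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(
        model.parameters(),
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    for _ in range(config.iterations):
        batch_idx = rng.choice(len(dataset_tuples), size=m, replace=False)
        z, z_hat = model.embed_tuples(
            [dataset_tuples[i] for i in batch_idx], training=False
        )
        loss = contrastive_loss_tensor(z, z_hat, config.tau)
        if config.lam > 0:
            loss = loss + config.lam * _ranking_loss_tensor(
                model, basis, feedback, graphs, config.delta
            )
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return model


def refresh_index(
    db: EmbeddedDatabase, model: ReactionEncoder, basis: ProjectionBasis | None = None
) -> EmbeddedDatabase:
    """Re-embed every database record with the updated model, same basis V."""
    return build_index(db.records, model, basis or db.basis)
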