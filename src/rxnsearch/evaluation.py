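"""Product-prediction metrics and the simulated user-feedback experiment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .encoder import ReactionEncoder
from .featurization import featurize_record
from .feedback import (
    FeedbackConfig,
    FeedbackEntry,
    QueryFeedbackSet,
    RatingVector,
    finetune,
    refresh_index,
)
from .pca_compress import ProjectionBasis, project
from .reaction_io import ReactionRecord
from .search import EmbeddedDatabase, QuerySpec, embed_query, retrieve_topk

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "ScenarioSpec",
    "FeedbackTrajectory",
    "ranks_from_embeddings",
    "metrics_from_ranks",
    "product_prediction_metrics",
    "halogen_set",
    "max_tanimoto",
    "rate_by_scenario",
    "simulate_feedback_loop",
]

HALOGENS = {"F", "Cl", "Br", "I"}  # astatine deliberately excluded


@dataclass
class MetricsReport:
    mrr: float
    mr: float
    hit_at: dict[int, float]
    n_queries: int

    def __post_init__(self):
        assert 0.0 <= self.mrr <= 1.0
        assert self.mr >= 1.0
        ks = sorted(self.hit_at)
        assert all(
            self.hit_at[a] <= self.hit_at[b] + 1e-12 for a, b in zip(ks, ks[1:])
        )


@dataclass
class ScenarioSpec:
    scenario_id: int
    tanimoto_threshold: float = 0.5
    default_reactant_count: int = 2
    halogen_multiset: bool = False  # compare counts instead of element sets

    def __post_init__(self):
        if self.scenario_id not in {1, 2, 3, 4, 5}:
            raise ValueError("scenario_id must be 1..5")
        if not 0.0 < self.tanimoto_threshold < 1.0:
            raise ValueError("tanimoto_threshold must lie in (0, 1)")


@dataclass
class FeedbackTrajectory:
    hit_ratios: list[float]  # index 0 is the pre-update state

    @property
    def rounds(self) -> int:
        return len(self.hit_ratios) - 1


def ranks_from_embeddings(
    query_vectors: np.ndarray, candidate_vectors: np.ndarray, truth_index: np.ndarray
) -> np.ndarray:
    """1-based rank of each query's true candidate by ascending distance.

    Ties are broken by candidate index so the ranking is deterministic.
    """
    truth_index = np.asarray(truth_index)
    ranks = np.empty(len(query_vectors), dtype=np.int64)
    for i, q in enumerate(np.asarray(query_vectors)):
        d = np.linalg.norm(np.asarray(candidate_vectors) - q, axis=1)
        order = np.lexsort((np.arange(len(d)), d))
        ranks[i] = int(np.where(order == truth_index[i])[0][0]) + 1
    return ranks


def metrics_from_ranks(
    ranks: Sequence[int], ks: Sequence[int] = (1, 3, 5, 10)
) -> MetricsReport:
    """MRR = mean(1/rank), MR = mean(rank), Hit@k = fraction with rank <= k."""
    ranks = np.asarray(ranks, dtype=np.float64)
    return MetricsReport(
        mrr=float(np.mean(1.0 / ranks)),
        mr=float(np.mean(ranks)),
        hit_at={k: float(np.mean(ranks <= k)) for k in ks},
        n_queries=len(ranks),
    )


def product_prediction_metrics(
    model: ReactionEncoder,
    test_records: Sequence[ReactionRecord],
    candidate_pool: Sequence[str] | None = None,
    basis: ProjectionBasis | None = None,
    ks: Sequence[int] = (1, 3, 5, 10),
    batch_size: int = 256,
) -> MetricsReport:
    """Rank the true product of each test reaction within a candidate pool.

    The pool defaults to the unique products of the test set. For each
    record, candidates are sorted by Euclidean distance between the record's
    prediction vector and each candidate's target vector; ties break on
    candidate-pool index. The rank of the ground-truth product gives MRR,
    MR and Hit@k.
    """
    test_records = list(test_records)
    if candidate_pool is None:
        seen = {}
        for r in test_records:
            seen.setdefault(r.product, None)
        candidate_pool = list(seen)
    pool_index = {smiles: i for i, smiles in enumerate(candidate_pool)}
    for r in test_records:
        if r.product not in pool_index:
            raise ValueError(
                f"ground-truth product of {r.record_id} missing from candidate pool"
            )

    pool_records = [
        ReactionRecord(record_id=f"pool{i}", product=s, reactants=[s])
        for i, s in enumerate(candidate_pool)
    ]

    def batched_embed(records, want):
        chunks = []
        for start in range(0, len(records), batch_size):
            tuples = [featurize_record(r) for r in records[start : start + batch_size]]
            z, z_hat = model.embed_tuples(tuples, training=False)
            chunks.append(z.data if want == "z" else z_hat.data)
        return np.vstack(chunks)

    pool_z = batched_embed(pool_records, "z")
    test_zhat = batched_embed(test_records, "z_hat")
    if basis is not None:
        pool_z = project(pool_z, basis)
        test_zhat = project(test_zhat, basis)

    truth = np.array([pool_index[r.product] for r in test_records])
    ranks = ranks_from_embeddings(test_zhat, pool_z, truth)
    return metrics_from_ranks(ranks, ks)


def halogen_set(smiles: str) -> frozenset[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return frozenset()
    return frozenset(
        a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() in HALOGENS
    )


def _halogen_counts(smiles: str) -> dict[str, int]:
    mol = Chem.MolFromSmiles(smiles)
    counts: dict[str, int] = {}
    if mol is None:
        return counts
    for a in mol.GetAtoms():
        if a.GetSymbol() in HALOGENS:
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
    return counts


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def fingerprint_bits(smiles: str) -> set[int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return set()
    return set(_FP_GEN.GetFingerprint(mol).GetOnBits())


def max_tanimoto(product: str, reactants: Sequence[str]) -> float:
    """Max Tanimoto similarity of the product against each reactant.

    Computed as |A&B| / |A|B| on 2048-bit radius-2 circular fingerprints.
    """
    if not reactants:
        raise ValueError("need at least one reactant")
    a = fingerprint_bits(product)
    best = 0.0
    for r in reactants:
        b = fingerprint_bits(r)
        union = len(a | b)
        if union:
            best = max(best, len(a & b) / union)
        elif not a and not b:
            best = max(best, 1.0)
    return best


def _halogen_condition(query_product: str, hit_product: str, scenario: ScenarioSpec) -> bool:
    if scenario.halogen_multiset:
        return _halogen_counts(hit_product) == _halogen_counts(query_product)
    return halogen_set(hit_product) == halogen_set(query_product)


def rate_by_scenario(
    query: QuerySpec, hit: ReactionRecord, scenario: ScenarioSpec
) -> int:
    """+1 iff the scenario predicate holds for the retrieved record, else -1.

    Scenario 1 compares the set of halogen element types in the two products
    (empty == empty counts as a match); 2 matches the reactant count of the
    query (default 2 when the query has no reactants); 3 thresholds the
    maximum product-reactant Tanimoto similarity; 4 and 5 are conjunctions
    of (1,2) and (1,3).
    """
    sid = scenario.scenario_id
    conds = []
    if sid in (1, 4, 5):
        if query.product is None:
            raise ValueError("scenario 1/4/5 requires a query product")
        conds.append(_halogen_condition(query.product, hit.product, scenario))
    if sid in (2, 4):
        target = (
            len(query.reactants) if query.reactants else scenario.default_reactant_count
        )
        conds.append(len(hit.reactants) == target)
    if sid in (3, 5):
        conds.append(
            max_tanimoto(hit.product, hit.reactants) > scenario.tanimoto_threshold
        )
    return +1 if all(conds) else -1


def simulate_feedback_loop(
    queries: Sequence[QuerySpec],
    db: EmbeddedDatabase,
    model: ReactionEncoder,
    basis: ProjectionBasis,
    scenario: ScenarioSpec,
    train_records: Sequence[ReactionRecord],
    K: int = 30,
    n_updates: int = 3,
    config: FeedbackConfig | None = None,
    accumulate: bool = True,
) -> FeedbackTrajectory:
    """Retrieve, rate by scenario, fine-tune, re-embed — repeated n_updates times.

    Returns the mean hit ratio (fraction of positively rated top-K hits
    across queries) per round; entry 0 is the pre-update state. With
    ``accumulate`` (default) the query set keeps the feedback of earlier
    rounds.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    config = config or FeedbackConfig()
    by_id = {r.record_id: r for r in db.records}
    feedback = QueryFeedbackSet()
    ratios: list[float] = []
    current_model, current_db = model, db

    for round_no in range(n_updates + 1):
        round_entries = []
        per_query_ratio = []
        for query in queries:
            x_star = embed_query(query, current_model, basis, current_db)
            result = retrieve_topk(x_star, current_db, None, K, query=query)
            ratings = [
                rate_by_scenario(query, by_id[rid], scenario)
                for rid, _ in result.hits
            ]
            per_query_ratio.append(
                float(np.mean([r == 1 for r in ratings])) if ratings else 0.0
            )
            round_entries.append(
                FeedbackEntry(
                    query=query, result=result, ratings=RatingVector(ratings)
                )
            )
        ratios.append(float(np.mean(per_query_ratio)))
        if round_no == n_updates:
            break
        if accumulate:
            feedback.extend(round_entries)
        else:
            feedback = QueryFeedbackSet(list(round_entries))
        round_config = FeedbackConfig(**{**config.__dict__, "seed": config.seed + round_no})
        current_model = finetune(
            current_model, train_records, feedback, round_config, basis, db=current_db
        )
        current_db = refresh_index(current_db, current_model, basis)
    return FeedbackTrajectory(hit_ratios=ratios)
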