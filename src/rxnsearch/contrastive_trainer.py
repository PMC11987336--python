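"""Contrastive training of the representation model.

The objective is a temperature-scaled cross-entropy (NT-Xent) over the 2M
stacked target/prediction vectors of a minibatch, with similarity given by
the negative squared Euclidean distance. The (z_i, z_hat_i) pair of each
record is the positive pair; all cross-record pairs are negatives, so a
minibatch of M records yields M positive and 2M(M-1) negative pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoder import EmbeddingPair, EncoderConfig, ReactionEncoder, init_model
from .featurization import ReactionGraphTuple, featurize_record
from .nn import Adam, Tensor, concat, gather_nd, gather_rows, logsumexp
from .reaction_io import ReactionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "pairwise_sq_euclidean",
    "nt_xent_euclid",
    "batch_objective",
    "contrastive_loss_tensor",
    "train",
]


@dataclass
class TrainConfig:
    tau: float = 100.0
    M: int = 4096
    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.M < 2:
            raise ValueError("minibatch size M must be at least 2")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def pairwise_sq_euclidean(vectors: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances (symmetric, zero diagonal)."""
    vectors = np.asarray(vectors, dtype=np.float64)
    sq = np.sum(vectors * vectors, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * vectors @ vectors.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def nt_xent_euclid(i: int, j: int, d2: np.ndarray, tau: float) -> float:
    """Contrastive loss l_c(i, j) over a precomputed distance matrix.

    The softmax denominator runs over all k != i (including k == j), with a
    max-shift before exponentiation for overflow safety.
    """
    if i == j:
        raise ValueError("i and j must differ")
    logits = -d2[i] / tau
    logits = np.delete(logits, i)
    shift = logits.max()
    log_denom = shift + math.log(np.exp(logits - shift).sum())
    return float(log_denom - (-d2[i, j] / tau))


def batch_objective(pairs: Sequence[EmbeddingPair], tau: float) -> float:
    """Symmetric NT-Xent objective J over a minibatch of embedding pairs."""
    m = len(pairs)
    z = np.stack([p.z for p in pairs] + [p.z_hat for p in pairs])
    d2 = pairwise_sq_euclidean(z)
    total = 0.0
    for i in range(m):
        total += nt_xent_euclid(i, m + i, d2, tau)
        total += nt_xent_euclid(m + i, i, d2, tau)
    return total / (2 * m)


_NEG_INF = -1e30


def contrastive_loss_tensor(z: Tensor, z_hat: Tensor, tau: float) -> Tensor:
    """Differentiable J for stacked target/prediction tensors (M x p each)."""
    m = z.shape[0]
    zcat = concat([z, z_hat], axis=0)
    sq = (zcat * zcat).sum(axis=1)
    d2 = sq.reshape(-1, 1) + sq.reshape(1, -1) - 2.0 * (zcat @ zcat.T)
    sims = d2 * (-1.0 / tau)
    sims = sims + Tensor(np.diag(np.full(2 * m, _NEG_INF)))  # exclude k == i
    lse = logsumexp(sims, axis=1)
    idx = np.arange(m)
    pos_upper = gather_nd(sims, idx, idx + m)
    pos_lower = gather_nd(sims, idx + m, idx)
    losses = (gather_rows(lse, idx) - pos_upper) + (
        gather_rows(lse, idx + m) - pos_lower
    )
    return losses.sum() * (1.0 / (2 * m))


def _evaluate_loss(
    model: ReactionEncoder,
    tuples: Sequence[ReactionGraphTuple],
    tau: float,
    batch_size: int,
) -> float:
    """Per-batch-averaged J over a dataset, in eval mode."""
    losses = []
    for start in range(0, len(tuples), batch_size):
        chunk = tuples[start : start + batch_size]
        if len(chunk) < 2:
            continue
        z, z_hat = model.embed_tuples(chunk, training=False)
        losses.append(contrastive_loss_tensor(z, z_hat, tau).item())
    return float(np.mean(losses)) if losses else float("nan")


def train(
    dataset: Sequence[ReactionRecord],
    val_dataset: Sequence[ReactionRecord],
    config: TrainConfig,
    encoder_config: EncoderConfig | None = None,
    model: ReactionEncoder | None = None,
) -> tuple[ReactionEncoder, TrainHistory]:
    """Train (or continue training) the representation model.

    Runs Adam on the contrastive objective with early stopping on the
    per-batch-averaged validation loss; returns the best-validation
    checkpoint and the epoch history. Fully seed-deterministic in
    single-threaded execution.
    """
    if not dataset or not val_dataset:
        raise ValueError("datasets must be non-empty")
    if model is None:
        model = init_model(encoder_config or EncoderConfig(seed=config.seed))
    m = config.M
    if m > len(dataset):
        logger.warning("M=%d larger than dataset (%d); clamping", m, len(dataset))
        m = len(dataset)

    train_tuples = [featurize_record(r) for r in dataset]
    val_tuples = [featurize_record(r) for r in val_dataset]

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    history = TrainHistory()
    best_val = float("inf")
    best_state = None
    epochs_since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_tuples))
        epoch_losses = []
        for start in range(0, len(order), m):
            batch_idx = order[start : start + m]
            if len(batch_idx) < 2:
                continue  # a single leftover record has no negatives
            z, z_hat = model.embed_tuples(
                [train_tuples[i] for i in batch_idx], training=True
            )
            loss = contrastive_loss_tensor(z, z_hat, config.tau)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        history.train_loss.append(float(np.mean(epoch_losses)))
        val_loss = _evaluate_loss(model, val_tuples, config.tau, m)
        history.val_loss.append(val_loss)
        logger.info(
            "epoch %d: train J=%.5f val J=%.5f",
            epoch,
            history.train_loss[-1],
            val_loss,
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
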