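"""Representation model: shared GIN encoder plus three projection heads.

The encoder is an edge-feature GIN: at every layer the message from
neighbor ``u`` over bond ``e`` is ``h_u + W_e x_e`` and the node update is
``MLP(h_v + sum of messages)`` followed by batch normalization (ReLU on all
but the last layer). The readout is sum pooling over each graph's nodes, so
disconnected molecule sets embed additively and stoichiometry is preserved.

The product path gives the target vector ``z``; the sum of the reactant-head
and reagent-head outputs gives the prediction vector ``z_hat``. Projection
heads are two affine layers with ReLU after the first; the final layer has
no bias so embeddings are approximately zero-centered over a database. A
record with no reagents contributes an exact zero vector on the reagent
branch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .featurization import (
    EDGE_FEATURE_DIM,
    FEATURE_MANIFEST,
    NODE_FEATURE_DIM,
    MolGraph,
    ReactionGraphTuple,
)
from .nn import BatchNorm, Linear, Tensor, gather_rows, segment_sum

__all__ = [
    "EncoderConfig",
    "EmbeddingPair",
    "GraphBatch",
    "ReactionEncoder",
    "init_model",
    "encode",
    "embed_record",
]


@dataclass
class EncoderConfig:
    gnn_layers: int = 5
    gnn_hidden: int = 300
    projection_hidden: int = 512
    p: int = 512
    readout: str = "sum"
    seed: int = 0

    def __post_init__(self):
        if min(self.gnn_layers, self.gnn_hidden, self.projection_hidden, self.p) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.readout != "sum":
            raise ValueError("readout is fixed to sum pooling")


@dataclass
class EmbeddingPair:
    """Target vector z and prediction vector z_hat for one record."""

    z: np.ndarray
    z_hat: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.z_hat = np.asarray(self.z_hat, dtype=np.float64)
        if self.z.shape != self.z_hat.shape:
            raise ValueError("z and z_hat must share dimensionality")
        if not (np.isfinite(self.z).all() and np.isfinite(self.z_hat).all()):
            raise ValueError("embedding vectors must be finite")


@dataclass
class GraphBatch:
    """Several molecule-set graphs packed into one disjoint union."""

    node_x: np.ndarray
    edge_src: np.ndarray  # directed: each bond appears in both directions
    edge_dst: np.ndarray
    edge_x: np.ndarray
    graph_ids: np.ndarray
    n_graphs: int
    node_counts: np.ndarray = field(default=None)

    @classmethod
    def from_graphs(cls, graphs: Sequence[MolGraph]) -> "GraphBatch":
        node_x, edge_x, src, dst, gids, counts = [], [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            node_x.append(g.node_features)
            gids.append(np.full(g.n_nodes, gi, dtype=np.int64))
            counts.append(g.n_nodes)
            if g.n_edges:
                u = g.edges[:, 0] + offset
                v = g.edges[:, 1] + offset
                src.append(np.concatenate([u, v]))
                dst.append(np.concatenate([v, u]))
                edge_x.append(np.concatenate([g.edge_features, g.edge_features]))
            offset += g.n_nodes
        cat = lambda parts, width: (
            np.concatenate(parts) if parts else np.zeros((0, width))
        )
        return cls(
            node_x=cat(node_x, NODE_FEATURE_DIM),
            edge_src=(
                np.concatenate(src) if src else np.zeros(0, dtype=np.int64)
            ),
            edge_dst=(
                np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64)
            ),
            edge_x=cat(edge_x, EDGE_FEATURE_DIM),
            graph_ids=(
                np.concatenate(gids) if gids else np.zeros(0, dtype=np.int64)
            ),
            n_graphs=len(graphs),
            node_counts=np.asarray(counts, dtype=np.int64),
        )


class _ProjectionHead:
    """Two affine layers, ReLU after the first, no bias on the last."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()

    def state(self, prefix):
        out = {f"{prefix}.fc1.{k}": v for k, v in self.fc1.state().items()}
        out.update({f"{prefix}.fc2.{k}": v for k, v in self.fc2.state().items()})
        return out

    def load_state(self, d, prefix):
        self.fc1.load_state(
            {k.split(".")[-1]: v for k, v in d.items() if k.startswith(f"{prefix}.fc1.")}
        )
        self.fc2.load_state(
            {k.split(".")[-1]: v for k, v in d.items() if k.startswith(f"{prefix}.fc2.")}
        )


class ReactionEncoder:
    """GIN encoder ``f`` shared by three projection heads (P, R, A)."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.manifest = dict(FEATURE_MANIFEST)
        rng = np.random.default_rng(config.seed)
        h = config.gnn_hidden
        self.node_in = Linear(NODE_FEATURE_DIM, h, rng)
        self.edge_lins = [Linear(EDGE_FEATURE_DIM, h, rng) for _ in range(config.gnn_layers)]
        self.mlps1 = [Linear(h, 2 * h, rng) for _ in range(config.gnn_layers)]
        self.mlps2 = [Linear(2 * h, h, rng) for _ in range(config.gnn_layers)]
        self.bns = [BatchNorm(h) for _ in range(config.gnn_layers)]
        self.head_p = _ProjectionHead(h, config.projection_hidden, config.p, rng)
        self.head_r = _ProjectionHead(h, config.projection_hidden, config.p, rng)
        self.head_a = _ProjectionHead(h, config.projection_hidden, config.p, rng)

    # ------------------------------------------------------------- parameters
    def parameters(self) -> list[Tensor]:
        params = self.node_in.parameters()
        for layer in range(self.config.gnn_layers):
            params += self.edge_lins[layer].parameters()
            params += self.mlps1[layer].parameters()
            params += self.mlps2[layer].parameters()
            params += self.bns[layer].parameters()
        for head in (self.head_p, self.head_r, self.head_a):
            params += head.parameters()
        return params

    # ---------------------------------------------------------------- forward
    def encode_batch(self, batch: GraphBatch, training: bool = False) -> Tensor:
        """Sum-pooled node representations per graph; empty graphs -> zero rows."""
        if batch.node_x.shape[0] == 0:
            return Tensor(np.zeros((batch.n_graphs, self.config.gnn_hidden)))
        if batch.node_x.shape[1] != NODE_FEATURE_DIM:
            raise ValueError("node feature dimensionality does not match manifest")
        h = self.node_in(Tensor(batch.node_x))
        n_nodes = batch.node_x.shape[0]
        for layer in range(self.config.gnn_layers):
            if batch.edge_src.size:
                e = self.edge_lins[layer](Tensor(batch.edge_x))
                msg = gather_rows(h, batch.edge_src) + e
                agg = h + segment_sum(msg, batch.edge_dst, n_nodes)
            else:
                agg = h
            h = self.mlps2[layer](self.mlps1[layer](agg).relu())
            h = self.bns[layer](h, training)
            if layer < self.config.gnn_layers - 1:
                h = h.relu()
        return segment_sum(h, batch.graph_ids, batch.n_graphs)

    def encode(self, graph: MolGraph, training: bool = False) -> np.ndarray:
        """Encode a single molecule-set graph to R^{gnn_hidden}."""
        return self.encode_batch(GraphBatch.from_graphs([graph]), training).data[0]

    def embed_tuples(
        self, tuples: Sequence[ReactionGraphTuple], training: bool = False
    ) -> tuple[Tensor, Tensor]:
        """Batched (z, z_hat) tensors for a list of reaction graph tuples.

        Records without reagents get an exact zero reagent contribution: the
        reagent branch is computed only for present reagent graphs and
        scattered back, leaving zero rows elsewhere.
        """
        n = len(tuples)
        z = self.head_p(
            self.encode_batch(
                GraphBatch.from_graphs([t.product_graph for t in tuples]), training
            )
        )
        z_hat = self.head_r(
            self.encode_batch(
                GraphBatch.from_graphs([t.reactant_graph for t in tuples]), training
            )
        )
        with_reagents = [i for i, t in enumerate(tuples) if t.reagent_graph is not None]
        if with_reagents:
            ga = self.head_a(
                self.encode_batch(
                    GraphBatch.from_graphs(
                        [tuples[i].reagent_graph for i in with_reagents]
                    ),
                    training,
                )
            )
            # scatter reagent contributions into an n-row tensor
            scatter = np.zeros((len(with_reagents), n))
            for row, i in enumerate(with_reagents):
                scatter[row, i] = 1.0
            z_hat = z_hat + ga.T.__matmul__(Tensor(scatter)).T
        return z, z_hat

    def embed_record(self, tup: ReactionGraphTuple) -> EmbeddingPair:
        z, z_hat = self.embed_tuples([tup], training=False)
        return EmbeddingPair(z=z.data[0], z_hat=z_hat.data[0])

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"node_in.{k}": v for k, v in self.node_in.state().items()}
        for layer in range(self.config.gnn_layers):
            for name, mod in (
                ("edge_lin", self.edge_lins[layer]),
                ("mlp1", self.mlps1[layer]),
                ("mlp2", self.mlps2[layer]),
                ("bn", self.bns[layer]),
            ):
                out.update(
                    {f"layer{layer}.{name}.{k}": v for k, v in mod.state().items()}
                )
        for prefix, head in (
            ("head_p", self.head_p),
            ("head_r", self.head_r),
            ("head_a", self.head_a),
        ):
            out.update(head.state(prefix))
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        self.node_in.load_state(
            {k.split(".")[-1]: v for k, v in d.items() if k.startswith("node_in.")}
        )
        for layer in range(self.config.gnn_layers):
            for name, mod in (
                ("edge_lin", self.edge_lins[layer]),
                ("mlp1", self.mlps1[layer]),
                ("mlp2", self.mlps2[layer]),
                ("bn", self.bns[layer]),
            ):
                prefix = f"layer{layer}.{name}."
                mod.load_state(
                    {k[len(prefix):]: v for k, v in d.items() if k.startswith(prefix)}
                )
        for prefix, head in (
            ("head_p", self.head_p),
            ("head_r", self.head_r),
            ("head_a", self.head_a),
        ):
            head.load_state(d, prefix)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        meta = {"config": asdict(self.config), "feature_manifest": self.manifest}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ReactionEncoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(EncoderConfig(**meta["config"]))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as archive:
            model.load_state_dict(dict(archive))
        return model

    def copy(self) -> "ReactionEncoder":
        clone = ReactionEncoder(self.config)
        clone.load_state_dict({k: v.copy() for k, v in self.state_dict().items()})
        return clone


def init_model(config: EncoderConfig) -> ReactionEncoder:
    return ReactionEncoder(config)


def encode(graph: MolGraph, model: ReactionEncoder) -> np.ndarray:
    return model.encode(graph)


def embed_record(tup: ReactionGraphTuple, model: ReactionEncoder) -> EmbeddingPair:
    return model.embed_record(tup)
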