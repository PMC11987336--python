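"""Principal-direction compression of target/prediction embeddings.

The basis is fit by SVD of the stacked 2N x p embedding matrix without
explicit mean-centering: the projection heads carry no bias on their final
layers, which approximately zero-centers the embeddings over a database, so
the projection stays a pure linear map and Euclidean distances in the
reduced space approximate (and at q = p equal) those in the original space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoder import EmbeddingPair

__all__ = [
    "ProjectionBasis",
    "stack_embeddings",
    "fit_basis",
    "project",
    "distance_preservation_report",
    "compression_rate",
]


@dataclass
class ProjectionBasis:
    V: np.ndarray  # p x q, orthonormal columns
    singular_values: np.ndarray  # length q, non-increasing
    explained_variance_ratio: np.ndarray  # per-component fractions
    q: int
    p: int
    threshold: float | None = None

    @property
    def cumulative_explained_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            V=self.V,
            singular_values=self.singular_values,
            explained_variance_ratio=self.explained_variance_ratio,
        )
        manifest = {
            "q": self.q,
            "p": self.p,
            "threshold": self.threshold,
            "centered": False,
            "singular_values": self.singular_values.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionBasis":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as arch:
            return cls(
                V=arch["V"],
                singular_values=arch["singular_values"],
                explained_variance_ratio=arch["explained_variance_ratio"],
                q=int(manifest["q"]),
                p=int(manifest["p"]),
                threshold=manifest.get("threshold"),
            )


def stack_embeddings(pairs: Sequence[EmbeddingPair]) -> np.ndarray:
    """Stack N pairs into a 2N x p matrix: targets first, then predictions."""
    if not pairs:
        raise ValueError("need at least one embedding pair")
    dims = {p.z.shape[0] for p in pairs}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding dimensionality: {sorted(dims)}")
    return np.vstack([[p.z for p in pairs], [p.z_hat for p in pairs]]).reshape(
        2 * len(pairs), -1
    )


def fit_basis(
    Z: np.ndarray,
    q: int | None = None,
    evr_threshold: float | None = None,
) -> ProjectionBasis:
    """Fit the p x q principal-direction matrix V by (uncentered) SVD of Z.

    Exactly one of ``q`` or ``evr_threshold`` selects the rank: a threshold
    picks the smallest q whose cumulative explained variance reaches it.
    Column signs are fixed so each direction's largest-magnitude entry is
    positive, making bases reproducible across SVD implementations.
    """
    Z = np.asarray(Z, dtype=np.float64)
    n2, p = Z.shape
    if (q is None) == (evr_threshold is None):
        raise ValueError("provide exactly one of q or evr_threshold")
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    energy = s**2
    evr = energy / energy.sum() if energy.sum() > 0 else np.zeros_like(energy)
    if evr_threshold is not None:
        if not 0.0 < evr_threshold <= 1.0:
            raise ValueError("evr_threshold must lie in (0, 1]")
        q = int(np.searchsorted(np.cumsum(evr), evr_threshold - 1e-12) + 1)
        q = min(q, len(s))
    if not 1 <= q <= min(n2, p):
        raise ValueError(f"q={q} outside [1, min(2N={n2}, p={p})]")
    V = vt[:q].T.copy()
    # deterministic sign convention
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(q)])
    flip[flip == 0] = 1.0
    V *= flip
    return ProjectionBasis(
        V=V,
        singular_values=s[:q].copy(),
        explained_variance_ratio=evr[:q].copy(),
        q=q,
        p=p,
        threshold=evr_threshold,
    )


def project(vectors: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Map vectors in R^p to R^q by right-multiplication with V."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape[-1] != basis.p:
        raise ValueError(
            f"expected vectors of dimension {basis.p}, got {vectors.shape[-1]}"
        )
    return vectors @ basis.V


def distance_preservation_report(
    vectors: np.ndarray,
    basis: ProjectionBasis,
    n_pairs: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Relative error |d_reduced - d_full| / d_full over sampled vector pairs."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, len(vectors), size=n_pairs)
    j = rng.integers(0, len(vectors), size=n_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    reduced = project(vectors, basis)
    d_full = np.linalg.norm(vectors[i] - vectors[j], axis=1)
    d_red = np.linalg.norm(reduced[i] - reduced[j], axis=1)
    valid = d_full > 0
    rel = np.abs(d_red[valid] - d_full[valid]) / d_full[valid]
    return {
        "max_rel_error": float(rel.max()) if rel.size else 0.0,
        "mean_rel_error": float(rel.mean()) if rel.size else 0.0,
        "n_pairs": int(valid.sum()),
    }


def compression_rate(p: int, q: int) -> float:
    """Fraction of stored coordinates eliminated by the projection, in percent."""
    if not 1 <= q <= p:
        raise ValueError("require 1 <= q <= p")
    return 100.0 * (1.0 - q / p)
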