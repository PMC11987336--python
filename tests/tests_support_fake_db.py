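"""Shared helper: wrap an explicit embedding matrix in an EmbeddedDatabase."""

import numpy as np

from rxnsearch.pca_compress import ProjectionBasis
from rxnsearch.reaction_io import ReactionRecord
from rxnsearch.search import EmbeddedDatabase


def make_fake_db(X: np.ndarray) -> EmbeddedDatabase:
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
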