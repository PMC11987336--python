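# rxnsearch

Feedback-driven chemical reaction search. Reaction records
(`reactants>reagents>products` SMILES plus optional condition/measurement
attributes) are embedded by a contrastively trained graph neural encoder,
compressed with a principal-direction basis, retrieved by Euclidean
distance, and iteratively refined from binary relevance ratings on search
results.

## How it works

- **Representation model** — a shared GIN encoder with edge features and sum
  pooling, plus three projection heads (product / reactants / reagents).
  The product path gives a *target vector* `z`; the sum of the reactant and
  reagent head outputs gives a *prediction vector* `z_hat`. Records without
  reagents contribute an exact zero on the reagent branch.
- **Contrastive training** — a temperature-scaled cross-entropy (NT-Xent)
  objective over the 2M stacked vectors of a minibatch, with similarity
  given by the negative squared Euclidean distance; the `(z, z_hat)` pair of
  each record is the positive pair.
- **Compression** — uncentered SVD of the stacked `2N x p` embedding matrix
  yields a `p x q` orthonormal basis (q chosen at a 95% explained-variance
  threshold by default); Euclidean distances in the reduced space
  approximate, and at `q = p` equal, full-space distances.
- **Search** — each record is stored as `x = [z' || z_hat']`; queries embed
  into the same space (substructure queries anchor on matching database
  records), candidates can be pre-filtered by attribute ranges, and the
  top-K nearest records are returned.
- **Feedback** — rated results feed a margin ranking loss blended with the
  contrastive objective; the model is fine-tuned with momentum SGD (batch
  norm frozen) and the database is re-embedded under the same basis.

The neural network and both training loops run on a small NumPy
reverse-mode autodiff core (`rxnsearch.nn`) — no GPU framework is required.

## CLI

```bash
rxnsearch fixtures --n 2000 --seed 7 --out fixtures/
rxnsearch train --data fixtures/train.csv --val fixtures/val.csv \
    --config train.yaml --seed 7 --out model.npz
rxnsearch fit-basis --data fixtures/train.csv --model model.npz \
    --evr-threshold 0.95 --out basis.npz
rxnsearch build-index --data fixtures/train.csv --model model.npz \
    --basis basis.npz --out index/
rxnsearch search --index index/ --product "CCOC(C)=O" --k 30 \
    --range yield:80:100 --out hits.csv
rxnsearch evaluate --model model.npz --test fixtures/test.csv --metrics m.json
rxnsearch simulate --index index/ --test fixtures/test.csv \
    --data fixtures/train.csv --scenario 2 --k 30 --updates 3 --seed 7 \
    --out trajectory.csv
```

Config files are YAML mirroring the defaults in `rxnsearch.config`
(temperature 100, minibatch 4096, learning rate 1e-4, weight decay 1e-8,
margin 100, ranking-loss weight 0.01, retrieval K 30). Every command writes
a JSON run manifest next to its output.

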