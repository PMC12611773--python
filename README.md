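# softalign

Human-aligned similarity spaces for embedding models: model human
odd-one-out uncertainty over triplets, align an embedding space to it with
a regularized affine transform, pseudo-label arbitrary triplets with the
aligned teacher, distil the similarity structure into a student encoder,
and evaluate alignment — all runnable offline on synthetic data.

## What's inside

| Module | Purpose |
| --- | --- |
| `softalign.triplets` | Dot-product triplet similarities, the softmax odd-one-out choice rule, accuracies, entropies |
| `softalign.synthetic` | Hierarchical ground-truth concept spaces (superordinate → basic → subordinate), simulated annotators (temperature + lapse), log-linear response times |
| `softalign.uncertainty` | Variational per-item mean/variance concept embeddings; Monte-Carlo triplet choice posteriors; fitting by analytic reparameterized gradients |
| `softalign.transform` | Affine alignment `x' = Wx + b` fit to soft pair-choice targets (mean KL) with a scaled-identity regularizer preserving nearest-neighbour structure |
| `softalign.sampling` | Random / class-boundary / cluster-boundary / stratified triplet sampling, seeded k-means with elbow selection, teacher pseudo-labelling |
| `softalign.distillation` | Dual-temperature KL distillation of teacher pair distributions into linear or MLP student encoders, with weight decay to initialization |
| `softalign.evaluation` | Odd-one-out accuracy vs. majority responses, RSA (Spearman over RSM upper triangles), leave-one-out noise ceilings, RT preprocessing, participant exclusion, hierarchical distance-change contrasts, item-level bootstrap CIs |
| `softalign.io` / `softalign.cli` | TSV/JSON readers and writers, the end-to-end pipeline CLI |

All optimization is NumPy with hand-derived analytic gradients (the losses
are softmaxes over three candidate pairs) and a small Adam implementation —
no autodiff framework required.

## CLI

Each stage reads a JSON config and writes fixed-name TSV artifacts plus a
manifest into the run directory:

```sh
softalign simulate        --config cfg.json   # ground truth, teacher space, responses
softalign fit-uncertainty --config cfg.json   # variational embedding from hard choices
softalign fit-transform   --config cfg.json   # affine alignment from soft targets
softalign sample          --config cfg.json   # triplets (random/class/cluster/levels)
softalign pseudolabel     --config cfg.json   # teacher soft + hard labels
softalign distill         --config cfg.json   # fine-tune the student encoder
softalign evaluate        --config cfg.json   # report.json / report.tsv
```

`--seed N` overrides the config seed, `--out DIR` the run directory. A
complete desk-scale config is exercised in `tests/test_io_cli.py`.

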