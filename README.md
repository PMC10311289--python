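# pockmol

Controllable, pocket-conditioned molecule generation. A dual-view 3D
binding-pocket encoder (residue-level and atom-level KNN graphs with
Gaussian-RBF edge embeddings, Laplacian positional encoding and
edge-augmented multi-head attention, fused one-way from atoms into
residues) feeds a property-conditioned autoregressive SMILES decoder
(masked self-attention, pocket-interactive cross-attention, top-k
sampling). Desired properties — a binarized binding-affinity bit plus
hard/soft drug-likeness properties — are injected as the first row of the
decoder input, so generation is steerable at sampling time.

The whole model runs on a small, fully-tested reverse-mode autodiff engine
over NumPy (`pockmol.nn`) — no deep-learning framework is required.

## Layout

| Module | Role |
| --- | --- |
| `pockmol.pocket_graphs` | PDB parsing, residue/atom KNN graphs, RBF edge embeddings, normalized-Laplacian positional features, node embedding |
| `pockmol.encoder` | edge-augmented multi-head self-attention units, one-way residue←atom cross-fusion, stacked pocket representation |
| `pockmol.codec` | BPE-style SMILES sub-token vocabulary, property binarization, sinusoidal positions, joint molecule embedding |
| `pockmol.decoder` | causal decoder blocks with pocket cross-attention, NLL loss, top-k sampling |
| `pockmol.model` | full generator: batched training loss, seeded generation (sampling + beam), versioned checkpoints |
| `pockmol.training` | Adam training loop with validation-driven lr decay (x0.6 after 5 stagnant validations, floor 1e-5) and early stopping (20) |
| `pockmol.evaluation` | validity, QED/SA/logP/TPSA/MW, Tanimoto diversity, high-affinity ratio, compliance; pluggable affinity-scorer seam |
| `pockmol.fixtures` | seeded synthetic pockets (helix-like PDB) and a conditioned SMILES corpus — no downloads needed |
| `pockmol.nn` | autodiff tensor, Adam, gradient clipping, dropout context |

## CLI

```bash
# synthetic fixtures: pockets as PDB + corpus as SMILES/TSV
pockmol make-fixtures --seed 0 --n-records 200 --out-dir fixtures/

# train on a synthetic conditioned corpus (YAML config)
pockmol train --config config.yaml --out-dir run/

# generate molecules for a pocket under explicit property conditions
pockmol generate --checkpoint run/checkpoint.npz --pocket fixtures/pocket_0.pdb \
    --properties "affinity=1,size=6" --n-samples 20 --top-k 5 --seed 0 \
    --out gen.smi

# metrics report (TSV): validity, diversity, descriptors, HAR via mock scorer
pockmol evaluate --generated gen.smi --scorer mock --out-dir eval/
```

A minimal training config:

```yaml
encoder: {n_units: 2, n_heads: 4, model_dim: 64, key_dim: 32, value_dim: 16,
          ffn_dim: 256, fusion_units: [1, 2]}
decoder: {n_blocks: 2, n_heads: 4, model_dim: 64, key_dim: 32, value_dim: 16,
          ffn_dim: 256, max_len: 40}
data: {n_records: 2000, n_pockets: 2, vocab_size: 3}
training: {batch_size: 4, max_steps: 2600, validate_every: 300, seed: 0,
           lr_init: 1.0e-3, cross_warmup_steps: 2000}
```

Full-scale defaults (6 units/blocks, d=256, 4 heads, k=30 residue / k=48
atom neighbors, 64 RBFs, 8 eigenvectors, 112-token vocabulary, max length
200, batch 4, lr 1e-4) are the dataclass defaults throughout.

`training.cross_warmup_steps` zero-initializes and temporarily freezes the
decoder's cross-attention output projections so the property-conditioning
circuit can form before pocket information joins; recommended for small
synthetic corpora where pockets carry no molecule signal.

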