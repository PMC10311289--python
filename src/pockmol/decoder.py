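"""Conditional autoregressive SMILES decoder.

Stacked decoding blocks: causal masked self-attention, pocket-interactive
cross-attention (molecule rows are queries, stacked pocket rows are keys and
values), and a feed-forward network — all with post-norm residuals. Trained
with token-level negative log-likelihood; generation is seeded top-k
sampling (optionally beam search).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass(frozen=True)
class DecoderConfig:
    n_blocks: int = 6
    n_heads: int = 4
    model_dim: int = 256
    key_dim: int = 32
    value_dim: int = 64
    ffn_dim: int = 1024
    max_len: int = 200
    dropout: float = 0.1

    def __post_init__(self):
        if self.n_heads * self.value_dim != self.model_dim:
            raise ValueError("n_heads * value_dim must equal model_dim")


def _xavier(rng, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def _norm_params(d: int) -> dict:
    return {
        "gain": Tensor(np.ones(d), requires_grad=True),
        "bias": Tensor(np.zeros(d), requires_grad=True),
    }


def _mha_params(rng, d: int, cfg: DecoderConfig) -> dict:
    H, dk, dv = cfg.n_heads, cfg.key_dim, cfg.value_dim
    return {
        "wq": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
        "wk": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
        "wv": Tensor(_xavier(rng, d, H * dv), requires_grad=True),
        "wo": Tensor(_xavier(rng, H * dv, d), requires_grad=True),
    }


def init_decoder_params(rng: np.random.Generator, cfg: DecoderConfig,
                        vocab_size: int) -> dict:
    d = cfg.model_dim
    params = {"blocks": []}
    for _ in range(cfg.n_blocks):
        params["blocks"].append(
            {
                "self": _mha_params(rng, d, cfg),
                "norm1": _norm_params(d),
                "cross": _mha_params(rng, d, cfg),
                "norm2": _norm_params(d),
                "ffn": {
                    "w1": Tensor(_xavier(rng, d, cfg.ffn_dim), requires_grad=True),
                    "b1": Tensor(np.zeros(cfg.ffn_dim), requires_grad=True),
                    "w2": Tensor(_xavier(rng, cfg.ffn_dim, d), requires_grad=True),
                    "b2": Tensor(np.zeros(d), requires_grad=True),
                },
                "norm3": _norm_params(d),
            }
        )
    params["w_out"] = Tensor(_xavier(rng, d, vocab_size), requires_grad=True)
    params["b_out"] = Tensor(np.zeros(vocab_size), requires_grad=True)
    return params


def _heads(t: Tensor, H: int) -> Tensor:
    # (B, L, H*dh) -> (B, H, L, dh)
    B, L, last = t.shape
    return t.reshape(B, L, H, last // H).transpose(0, 2, 1, 3)


def _merge_heads(t: Tensor) -> Tensor:
    # (B, H, L, dv) -> (B, L, H*dv)
    B, H, L, dv = t.shape
    return t.transpose(0, 2, 1, 3).reshape(B, L, H * dv)


def _self_attention(h: Tensor, p: dict, cfg: DecoderConfig) -> Tensor:
    B, L, _ = h.shape
    q = _heads(h @ p["wq"], cfg.n_heads)
    k = _heads(h @ p["wk"], cfg.n_heads)
    v = _heads(h @ p["wv"], cfg.n_heads)
    logits = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(cfg.key_dim)  # (B,H,L,L)
    causal = np.tril(np.ones((L, L), dtype=bool))[None, None]
    weights = T.masked_softmax(logits, causal, axis=-1)
    return _merge_heads(weights @ v) @ p["wo"]


def _cross_attention(h: Tensor, pocket: Tensor, pocket_mask: np.ndarray,
                     p: dict, cfg: DecoderConfig) -> Tensor:
    q = _heads(h @ p["wq"], cfg.n_heads)  # (B,H,L,dk)
    k = _heads(pocket @ p["wk"], cfg.n_heads)  # (B,H,P,dk)
    v = _heads(pocket @ p["wv"], cfg.n_heads)
    logits = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(cfg.key_dim)  # (B,H,L,P)
    mask = np.asarray(pocket_mask, bool)[:, None, None, :]
    weights = T.masked_softmax(logits, mask, axis=-1)
    return _merge_heads(weights @ v) @ p["wo"]


def decoder_forward_batch(h0: Tensor, pocket: Tensor, pocket_mask: np.ndarray,
                          params: dict, cfg: DecoderConfig) -> Tensor:
    """Batched decoder: h0 (B, L, d), pocket (B, P, d) -> logits (B, L, V)."""
    h = h0
    for block in params["blocks"]:
        a = T.maybe_dropout(_self_attention(h, block["self"], cfg), cfg.dropout)
        h = T.layer_norm(h + a, block["norm1"]["gain"], block["norm1"]["bias"])
        c = T.maybe_dropout(
            _cross_attention(h, pocket, pocket_mask, block["cross"], cfg),
            cfg.dropout,
        )
        h = T.layer_norm(h + c, block["norm2"]["gain"], block["norm2"]["bias"])
        ffn = block["ffn"]
        inner = ((h @ ffn["w1"]) + ffn["b1"]).relu() @ ffn["w2"] + ffn["b2"]
        inner = T.maybe_dropout(inner, cfg.dropout)
        h = T.layer_norm(h + inner, block["norm3"]["gain"], block["norm3"]["bias"])
    return h @ params["w_out"] + params["b_out"]


def decoder_forward(h0, pocket_rep, params: dict, cfg: DecoderConfig,
                    pocket_mask: np.ndarray | None = None):
    """Single-sequence decoder forward: h0 (L, d) -> logits (L, vocab_size)."""
    h0 = T.as_tensor(h0)
    pocket_matrix = getattr(pocket_rep, "matrix", pocket_rep)
    pocket_matrix = T.as_tensor(pocket_matrix)
    if pocket_mask is None:
        pocket_mask = getattr(pocket_rep, "mask",
                              np.ones(pocket_matrix.shape[0], dtype=bool))
    if h0.ndim != 2 or pocket_matrix.ndim != 2:
        raise ValueError("decoder_forward expects 2-D h0 and pocket matrices")
    if pocket_matrix.shape[0] != len(pocket_mask):
        raise ValueError("pocket mask length does not match pocket rows")
    L, d = h0.shape
    logits = decoder_forward_batch(
        h0.reshape(1, L, d),
        pocket_matrix.reshape(1, *pocket_matrix.shape),
        np.asarray(pocket_mask, bool)[None, :],
        params,
        cfg,
    )
    return logits.reshape(L, logits.shape[-1])


def nll_loss(logits, targets: np.ndarray, mask: np.ndarray | None = None,
             reduction: str = "mean"):
    """Negative log-likelihood of `targets` under `logits`.

    logits: (..., L, V); targets: (..., L) int ids; mask selects the scored
    positions (pad and conditioning rows excluded by the caller).
    """
    logits = T.as_tensor(logits)
    targets = np.asarray(targets)
    if mask is None:
        mask = np.ones(targets.shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("all positions are masked out of the loss")
    lp = T.log_softmax(logits, axis=-1)
    idx = np.nonzero(mask)
    picked = lp[(*idx, targets[idx])]
    total = -picked.sum()
    if reduction == "mean":
        return total / int(mask.sum())
    if reduction == "sum":
        return total
    raise ValueError("reduction must be 'mean' or 'sum'")


def build_targets(token_id_seqs: list[list[int]], L: int, end_id: int,
                  pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Teacher-forcing targets for h0 rows [prop, b, a_1..a_n, pad...].

    Row i predicts the successor of its token: row 1 (begin) -> a_1, ...,
    row n+1 (a_n) -> end tag. Row 0 (property) and pad rows are unscored.
    """
    B = len(token_id_seqs)
    targets = np.full((B, L), pad_id, dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    for b, seq in enumerate(token_id_seqs):
        n = len(seq)
        targets[b, 1 : n + 1] = seq
        targets[b, n + 1] = end_id
        mask[b, 1 : n + 2] = True
    return targets, mask


def sample_next(logits: np.ndarray, top_k: int, temperature: float,
                rng: np.random.Generator) -> tuple[int, float]:
    """Draw the next token from the renormalized top-k distribution.

    Returns (token id, log-probability under the full temperature-adjusted
    softmax). top_k=1 is greedy argmax (lowest index on ties).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=float) / temperature
    z = z - z.max()
    logp = z - np.log(np.exp(z).sum())
    k = min(top_k, z.size)
    # ties at the cutoff broken by ascending index
    order = np.lexsort((np.arange(z.size), -z))
    top = order[:k]
    if k == 1:
        choice = int(top[0])
    else:
        p = np.exp(logp[top])
        p /= p.sum()
        choice = int(rng.choice(top, p=p))
    return choice, float(logp[choice])
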