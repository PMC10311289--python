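"""Dual-view pocket encoder.

Two parallel stacks of edge-augmented multi-head self-attention units encode
the residue graph and the atom graph; one-way cross-fusion blocks let residue
representations attend over all atom representations at selected depths. The
final pocket representation vertically stacks the two views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor
from .pocket_graphs import (
    GraphConfig,
    PositionalFeatures,
    SpatialGraph,
    embed_graph_nodes,
    laplacian_positional_features,
    rbf_encode,
)


@dataclass(frozen=True)
class EncoderConfig:
    n_units: int = 6
    n_heads: int = 4
    model_dim: int = 256
    key_dim: int = 32
    value_dim: int = 64
    ffn_dim: int = 1024
    fusion_units: tuple[int, ...] = (3, 6)
    fusion_heads: int = 4
    edge_dim: int = 64
    dropout: float = 0.1

    def __post_init__(self):
        if self.n_heads * self.value_dim != self.model_dim:
            raise ValueError("n_heads * value_dim must equal model_dim")
        if any(u < 1 or u > self.n_units for u in self.fusion_units):
            raise ValueError("fusion_units must lie in 1..n_units")


@dataclass
class PocketRepresentation:
    """Stacked [residue; atom] encoder output with a row-validity mask."""

    matrix: object  # (n_res + n_atom, d) Tensor or ndarray
    mask: np.ndarray  # (n_res + n_atom,) bool
    n_residues: int
    n_atoms: int


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def _attention_params(rng, d: int, edge_dim: int, cfg: EncoderConfig) -> dict:
    H, dk, dv = cfg.n_heads, cfg.key_dim, cfg.value_dim
    return {
        "wq": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
        "wk": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
        "wv": Tensor(_xavier(rng, d, H * dv), requires_grad=True),
        "we_q": Tensor(_xavier(rng, edge_dim, H * dk), requires_grad=True),
        "we_k": Tensor(_xavier(rng, edge_dim, H * dk), requires_grad=True),
        "we_v": Tensor(_xavier(rng, edge_dim, H * dv), requires_grad=True),
        "wo": Tensor(_xavier(rng, H * dv, d), requires_grad=True),
    }


def _ffn_params(rng, d: int, ffn_dim: int) -> dict:
    return {
        "w1": Tensor(_xavier(rng, d, ffn_dim), requires_grad=True),
        "b1": Tensor(np.zeros(ffn_dim), requires_grad=True),
        "w2": Tensor(_xavier(rng, ffn_dim, d), requires_grad=True),
        "b2": Tensor(np.zeros(d), requires_grad=True),
    }


def _norm_params(d: int) -> dict:
    return {
        "gain": Tensor(np.ones(d), requires_grad=True),
        "bias": Tensor(np.zeros(d), requires_grad=True),
    }


def init_view_params(rng: np.random.Generator, cfg: EncoderConfig,
                     node_dim: int, n_eigenvectors: int) -> dict:
    """Parameters for one view: input projections plus n_units unit stacks."""
    d = cfg.model_dim
    params = {
        "w_node": Tensor(_xavier(rng, node_dim, d), requires_grad=True),
        "w_pos": Tensor(_xavier(rng, n_eigenvectors, d), requires_grad=True),
        "units": [],
    }
    for _ in range(cfg.n_units):
        params["units"].append(
            {
                "attn": _attention_params(rng, d, cfg.edge_dim, cfg),
                "norm1": _norm_params(d),
                "ffn": _ffn_params(rng, d, cfg.ffn_dim),
                "norm2": _norm_params(d),
            }
        )
    return params


def init_fusion_params(rng: np.random.Generator, cfg: EncoderConfig) -> dict:
    d, H, dk, dv = cfg.model_dim, cfg.fusion_heads, cfg.key_dim, cfg.value_dim
    return {
        str(unit): {
            "wq": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
            "wk": Tensor(_xavier(rng, d, H * dk), requires_grad=True),
            "wv": Tensor(_xavier(rng, d, H * dv), requires_grad=True),
            "wo": Tensor(_xavier(rng, H * dv, d), requires_grad=True),
            "norm": _norm_params(d),
        }
        for unit in cfg.fusion_units
    }


def init_encoder_params(rng: np.random.Generator, cfg: EncoderConfig,
                        n_eigenvectors: int = 8) -> dict:
    return {
        "residue": init_view_params(rng, cfg, 20, n_eigenvectors),
        "atom": init_view_params(rng, cfg, 7, n_eigenvectors),
        "fusion": init_fusion_params(rng, cfg),
    }


# ---------------------------------------------------------------------------
# Attention primitives
# ---------------------------------------------------------------------------

def _split_heads(t: Tensor, n_heads: int) -> Tensor:
    # (..., H*dh) -> (..., H, dh)
    *lead, last = t.shape
    return t.reshape(*lead, n_heads, last // n_heads)


def edge_augmented_scores(h_prev: Tensor, graph: SpatialGraph,
                          edge_emb: np.ndarray, attn: dict,
                          cfg: EncoderConfig):
    """Neighbor-specific (q_ij, k_ij, v_ij) triples.

    q_ij = q_i * (e_ij We_Q), k_ij = k_{N_i(j)} * (e_ij We_K),
    v_ij = v_{N_i(j)} * (e_ij We_V), elementwise per head.
    Shapes: (n, k, H, d_k) / (n, k, H, d_v).
    """
    H = cfg.n_heads
    if edge_emb.shape[:2] != graph.neighborhoods.shape:
        raise ValueError("edge embeddings missing for some directed edge")
    q = _split_heads(h_prev @ attn["wq"], H)  # (n, H, dk)
    k = _split_heads(h_prev @ attn["wk"], H)
    v = _split_heads(h_prev @ attn["wv"], H)
    e = Tensor(edge_emb)  # (n, k, de)
    eq = _split_heads(e @ attn["we_q"], H)  # (n, k, H, dk)
    ek = _split_heads(e @ attn["we_k"], H)
    ev = _split_heads(e @ attn["we_v"], H)
    nbr = graph.neighborhoods
    q_ij = q.expand_dims(1) * eq  # broadcast (n,1,H,dk)*(n,k,H,dk)
    k_ij = k[nbr] * ek  # gather neighbor keys: (n,k,H,dk)
    v_ij = v[nbr] * ev
    return q_ij, k_ij, v_ij


def neighborhood_attention(q_ij: Tensor, k_ij: Tensor, v_ij: Tensor,
                           cfg: EncoderConfig) -> Tensor:
    """Per-head softmax over each node's neighborhood; heads concatenated."""
    if q_ij.shape[1] == 0:
        raise ValueError("empty neighborhood")
    logits = (q_ij * k_ij).sum(axis=-1) / np.sqrt(cfg.key_dim)  # (n, k, H)
    weights = T.softmax(logits, axis=1)
    out = (weights.expand_dims(-1) * v_ij).sum(axis=1)  # (n, H, dv)
    n = out.shape[0]
    return out.reshape(n, cfg.n_heads * cfg.value_dim)


def encoder_unit(h_prev: Tensor, graph: SpatialGraph, edge_emb: np.ndarray,
                 unit_params: dict, cfg: EncoderConfig) -> Tensor:
    """One encoding unit: edge-augmented attention then FFN, post-norm residuals."""
    q_ij, k_ij, v_ij = edge_augmented_scores(h_prev, graph, edge_emb,
                                             unit_params["attn"], cfg)
    attended = neighborhood_attention(q_ij, k_ij, v_ij, cfg)
    update = T.maybe_dropout(attended @ unit_params["attn"]["wo"], cfg.dropout)
    h = T.layer_norm(update + h_prev,
                     unit_params["norm1"]["gain"], unit_params["norm1"]["bias"])
    ffn = unit_params["ffn"]
    inner = ((h @ ffn["w1"]) + ffn["b1"]).relu() @ ffn["w2"] + ffn["b2"]
    inner = T.maybe_dropout(inner, cfg.dropout)
    return T.layer_norm(inner + h,
                        unit_params["norm2"]["gain"], unit_params["norm2"]["bias"])


def cross_fusion(h_residue: Tensor, z_atom: Tensor, fusion_params: dict,
                 cfg: EncoderConfig,
                 atom_mask: np.ndarray | None = None) -> Tensor:
    """One-way fusion: residues (queries) attend over all atoms (keys/values).

    Atom representations are not updated. Residual + LayerNorm, no FFN.
    """
    n_atoms = z_atom.shape[0]
    if n_atoms == 0:
        raise ValueError("empty atom view")
    H, dk, dv = cfg.fusion_heads, cfg.key_dim, cfg.value_dim
    q = _split_heads(h_residue @ fusion_params["wq"], H)  # (nr, H, dk)
    k = _split_heads(z_atom @ fusion_params["wk"], H)  # (na, H, dk)
    v = _split_heads(z_atom @ fusion_params["wv"], H)
    logits = (q.transpose(1, 0, 2) @ k.transpose(1, 2, 0)) / np.sqrt(dk)  # (H, nr, na)
    if atom_mask is not None:
        weights = T.masked_softmax(logits, np.asarray(atom_mask, bool)[None, None, :],
                                   axis=-1)
    else:
        weights = T.softmax(logits, axis=-1)
    fused = weights @ v.transpose(1, 0, 2)  # (H, nr, dv)
    n_res = h_residue.shape[0]
    fused = fused.transpose(1, 0, 2).reshape(n_res, H * dv)
    update = fused @ fusion_params["wo"]
    return T.layer_norm(h_residue + update,
                        fusion_params["norm"]["gain"], fusion_params["norm"]["bias"])


def encode_view_input(graph: SpatialGraph, positional: PositionalFeatures,
                      view_params: dict) -> Tensor:
    return embed_graph_nodes(graph, positional, view_params["w_node"],
                             view_params["w_pos"])


def encode_pocket(residue_graph: SpatialGraph, atom_graph: SpatialGraph,
                  params: dict, cfg: EncoderConfig,
                  residue_graph_config: GraphConfig,
                  atom_graph_config: GraphConfig,
                  residue_positional: PositionalFeatures | None = None,
                  atom_positional: PositionalFeatures | None = None,
                  residue_edges: np.ndarray | None = None,
                  atom_edges: np.ndarray | None = None
                  ) -> PocketRepresentation:
    """Run both view stacks in lockstep, fusing at the configured units.

    Fusion updates only the residue view and is applied after a unit's
    attention + FFN blocks, before the next unit.
    """
    if residue_positional is None:
        residue_positional = laplacian_positional_features(residue_graph,
                                                           residue_graph_config)
    if atom_positional is None:
        atom_positional = laplacian_positional_features(atom_graph,
                                                        atom_graph_config)
    res_edges = residue_edges if residue_edges is not None else \
        rbf_encode(residue_graph.edge_distances, residue_graph_config)
    if atom_edges is None:
        atom_edges = rbf_encode(atom_graph.edge_distances, atom_graph_config)

    h = encode_view_input(residue_graph, residue_positional, params["residue"])
    z = encode_view_input(atom_graph, atom_positional, params["atom"])
    for unit in range(1, cfg.n_units + 1):
        h = encoder_unit(h, residue_graph, res_edges,
                         params["residue"]["units"][unit - 1], cfg)
        z = encoder_unit(z, atom_graph, atom_edges,
                         params["atom"]["units"][unit - 1], cfg)
        if unit in cfg.fusion_units:
            h = cross_fusion(h, z, params["fusion"][str(unit)], cfg)
    matrix = T.concatenate([h, z], axis=0)
    n_res, n_atom = residue_graph.n_nodes, atom_graph.n_nodes
    mask = np.ones(n_res + n_atom, dtype=bool)
    return PocketRepresentation(matrix=matrix, mask=mask,
                                n_residues=n_res, n_atoms=n_atom)
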