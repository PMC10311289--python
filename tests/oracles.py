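"""Naive loop-based reference implementations (oracles) for the attention
stacks. Pure NumPy, one node/head/edge at a time — deliberately independent
of the vectorized autodiff path they are used to check."""

import numpy as np


def _softmax(v):
    e = np.exp(v - np.max(v))
    return e / e.sum()


def _layer_norm(row, gain, bias, eps=1e-5):
    mu = row.mean()
    var = ((row - mu) ** 2).mean()
    return (row - mu) / np.sqrt(var + eps) * gain + bias


def _d(t):
    return t.data if hasattr(t, "data") else np.asarray(t)


def ref_edge_triples(h, graph, edge_emb, attn, cfg):
    """Per-edge (q_ij, k_ij, v_ij), one edge and head at a time."""
    n, k = graph.neighborhoods.shape
    H, dk, dv = cfg.n_heads, cfg.key_dim, cfg.value_dim
    wq, wk, wv = _d(attn["wq"]), _d(attn["wk"]), _d(attn["wv"])
    weq, wek, wev = _d(attn["we_q"]), _d(attn["we_k"]), _d(attn["we_v"])
    q_ij = np.zeros((n, k, H, dk))
    k_ij = np.zeros((n, k, H, dk))
    v_ij = np.zeros((n, k, H, dv))
    for i in range(n):
        for slot in range(k):
            j = graph.neighborhoods[i, slot]
            e = edge_emb[i, slot]
            for r in range(H):
                qi = h[i] @ wq[:, r * dk:(r + 1) * dk]
                kj = h[j] @ wk[:, r * dk:(r + 1) * dk]
                vj = h[j] @ wv[:, r * dv:(r + 1) * dv]
                q_ij[i, slot, r] = qi * (e @ weq[:, r * dk:(r + 1) * dk])
                k_ij[i, slot, r] = kj * (e @ wek[:, r * dk:(r + 1) * dk])
                v_ij[i, slot, r] = vj * (e @ wev[:, r * dv:(r + 1) * dv])
    return q_ij, k_ij, v_ij


def ref_neighborhood_attention(q_ij, k_ij, v_ij, cfg):
    n, k, H, dk = q_ij.shape
    dv = v_ij.shape[-1]
    out = np.zeros((n, H * dv))
    for i in range(n):
        per_head = []
        for r in range(H):
            logits = np.array([
                q_ij[i, slot, r] @ k_ij[i, slot, r] / np.sqrt(dk)
                for slot in range(k)
            ])
            w = _softmax(logits)
            assert abs(w.sum() - 1.0) < 1e-6
            acc = np.zeros(dv)
            for slot in range(k):
                acc += w[slot] * v_ij[i, slot, r]
            per_head.append(acc)
        out[i] = np.concatenate(per_head)
    return out


def ref_encoder_unit(h, graph, edge_emb, unit_params, cfg):
    q_ij, k_ij, v_ij = ref_edge_triples(h, graph, edge_emb,
                                        unit_params["attn"], cfg)
    attended = ref_neighborhood_attention(q_ij, k_ij, v_ij, cfg)
    wo = _d(unit_params["attn"]["wo"])
    g1, b1 = _d(unit_params["norm1"]["gain"]), _d(unit_params["norm1"]["bias"])
    g2, b2 = _d(unit_params["norm2"]["gain"]), _d(unit_params["norm2"]["bias"])
    ffn = unit_params["ffn"]
    out = np.zeros_like(h)
    for i in range(h.shape[0]):
        row = _layer_norm(attended[i] @ wo + h[i], g1, b1)
        inner = np.maximum(row @ _d(ffn["w1"]) + _d(ffn["b1"]), 0.0)
        inner = inner @ _d(ffn["w2"]) + _d(ffn["b2"])
        out[i] = _layer_norm(inner + row, g2, b2)
    return out


def ref_cross_fusion(h_res, z_atom, fp, cfg):
    H, dk, dv = cfg.fusion_heads, cfg.key_dim, cfg.value_dim
    wq, wk, wv, wo = _d(fp["wq"]), _d(fp["wk"]), _d(fp["wv"]), _d(fp["wo"])
    g, b = _d(fp["norm"]["gain"]), _d(fp["norm"]["bias"])
    n_res, n_atom = h_res.shape[0], z_atom.shape[0]
    out = np.zeros_like(h_res)
    for i in range(n_res):
        per_head = []
        for r in range(H):
            qi = h_res[i] @ wq[:, r * dk:(r + 1) * dk]
            logits = np.array([
                qi @ (z_atom[j] @ wk[:, r * dk:(r + 1) * dk]) / np.sqrt(dk)
                for j in range(n_atom)
            ])
            w = _softmax(logits)
            acc = np.zeros(dv)
            for j in range(n_atom):
                acc += w[j] * (z_atom[j] @ wv[:, r * dv:(r + 1) * dv])
            per_head.append(acc)
        update = np.concatenate(per_head) @ wo
        out[i] = _layer_norm(h_res[i] + update, g, b)
    return out


def ref_encode_pocket(res_graph, atom_graph, res_pos, atom_pos,
                      res_edges, atom_edges, params, cfg):
    h = (res_graph.node_features @ _d(params["residue"]["w_node"])
         + res_pos.vectors @ _d(params["residue"]["w_pos"]))
    z = (atom_graph.node_features @ _d(params["atom"]["w_node"])
         + atom_pos.vectors @ _d(params["atom"]["w_pos"]))
    for unit in range(1, cfg.n_units + 1):
        h = ref_encoder_unit(h, res_graph, res_edges,
                             params["residue"]["units"][unit - 1], cfg)
        z = ref_encoder_unit(z, atom_graph, atom_edges,
                             params["atom"]["units"][unit - 1], cfg)
        if unit in cfg.fusion_units:
            h = ref_cross_fusion(h, z, params["fusion"][str(unit)], cfg)
    return np.vstack([h, z])


def ref_decoder_forward(h0, pocket, params, cfg):
    """Loop decoder: causal self-attention, cross-attention, FFN per row."""
    H, dk, dv = cfg.n_heads, cfg.key_dim, cfg.value_dim
    h = np.array(h0, dtype=float)
    L = h.shape[0]
    P = pocket.shape[0]
    for block in params["blocks"]:
        sp = block["self"]
        nxt = np.zeros_like(h)
        for i in range(L):
            per_head = []
            for r in range(H):
                qi = h[i] @ _d(sp["wq"])[:, r * dk:(r + 1) * dk]
                logits = np.array([
                    qi @ (h[j] @ _d(sp["wk"])[:, r * dk:(r + 1) * dk])
                    / np.sqrt(dk)
                    for j in range(i + 1)
                ])
                w = _softmax(logits)
                acc = np.zeros(dv)
                for j in range(i + 1):
                    acc += w[j] * (h[j] @ _d(sp["wv"])[:, r * dv:(r + 1) * dv])
                per_head.append(acc)
            nxt[i] = _layer_norm(
                h[i] + np.concatenate(per_head) @ _d(sp["wo"]),
                _d(block["norm1"]["gain"]), _d(block["norm1"]["bias"]))
        h = nxt
        cp = block["cross"]
        nxt = np.zeros_like(h)
        for i in range(L):
            per_head = []
            for r in range(H):
                qi = h[i] @ _d(cp["wq"])[:, r * dk:(r + 1) * dk]
                logits = np.array([
                    qi @ (pocket[j] @ _d(cp["wk"])[:, r * dk:(r + 1) * dk])
                    / np.sqrt(dk)
                    for j in range(P)
                ])
                w = _softmax(logits)
                acc = np.zeros(dv)
                for j in range(P):
                    acc += w[j] * (pocket[j] @ _d(cp["wv"])[:, r * dv:(r + 1) * dv])
                per_head.append(acc)
            nxt[i] = _layer_norm(
                h[i] + np.concatenate(per_head) @ _d(cp["wo"]),
                _d(block["norm2"]["gain"]), _d(block["norm2"]["bias"]))
        h = nxt
        ffn = block["ffn"]
        nxt = np.zeros_like(h)
        for i in range(L):
            inner = np.maximum(h[i] @ _d(ffn["w1"]) + _d(ffn["b1"]), 0.0)
            inner = inner @ _d(ffn["w2"]) + _d(ffn["b2"])
            nxt[i] = _layer_norm(h[i] + inner,
                                 _d(block["norm3"]["gain"]),
                                 _d(block["norm3"]["bias"]))
        h = nxt
    return h @ _d(params["w_out"]) + _d(params["b_out"])
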