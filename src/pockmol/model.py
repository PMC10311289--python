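"""Full generator model: pocket encoder + molecule embedding + decoder.

Holds every learnable parameter, precomputes per-pocket graph inputs once,
and provides batched training loss, seeded top-k generation and a versioned
checkpoint format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import codec
from .codec import (
    MoleculeEmbeddingParams,
    MoleculeRecord,
    PropertyRule,
    PropertySchema,
    Vocabulary,
    embed_molecule_batch,
    init_embedding_params,
)
from .decoder import (
    DecoderConfig,
    build_targets,
    decoder_forward_batch,
    init_decoder_params,
    nll_loss,
    sample_next,
)
from .encoder import (
    EncoderConfig,
    PocketRepresentation,
    encode_pocket,
    init_encoder_params,
)
from .nn import tensor as T
from .nn.tensor import Tensor
from .pocket_graphs import (
    GraphConfig,
    PocketStructure,
    atom_graph,
    laplacian_positional_features,
    residue_graph,
)

CHECKPOINT_VERSION = 1


@dataclass
class PocketInputs:
    """Precomputed, parameter-free pocket inputs (graphs + spectral features)."""

    residue_graph: object
    atom_graph: object
    residue_positional: object
    atom_positional: object
    residue_edges: np.ndarray | None = None
    atom_edges: np.ndarray | None = None


@dataclass
class GenerationRequest:
    pocket: PocketRepresentation
    y_desired: np.ndarray
    top_k: int = 5
    temperature: float = 1.0
    n_samples: int = 10
    seed: int = 0
    max_len: int = 200

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class GeneratedMolecule:
    smiles: str
    token_ids: list[int]
    log_prob: float
    termination: str  # "end_tag" | "max_len"


@dataclass
class GeneratedSet:
    molecules: list[GeneratedMolecule]


def _flatten_params(tree, prefix: str = "") -> dict[str, Tensor]:
    flat: dict[str, Tensor] = {}
    if isinstance(tree, Tensor):
        flat[prefix.rstrip("/")] = tree
    elif isinstance(tree, MoleculeEmbeddingParams):
        for name in ("w_prop", "w_token", "t_prop", "t_word"):
            flat[f"{prefix}{name}"] = getattr(tree, name)
    elif isinstance(tree, dict):
        for key, val in tree.items():
            flat.update(_flatten_params(val, f"{prefix}{key}/"))
    elif isinstance(tree, (list, tuple)):
        for i, val in enumerate(tree):
            flat.update(_flatten_params(val, f"{prefix}{i}/"))
    return flat


class GeneratorModel:
    def __init__(self, vocab: Vocabulary, schema: PropertySchema,
                 residue_cfg: GraphConfig, atom_cfg: GraphConfig,
                 encoder_cfg: EncoderConfig, decoder_cfg: DecoderConfig,
                 params: dict):
        if encoder_cfg.model_dim != decoder_cfg.model_dim:
            raise ValueError("encoder and decoder model dims must match")
        self.vocab = vocab
        self.schema = schema
        self.residue_cfg = residue_cfg
        self.atom_cfg = atom_cfg
        self.encoder_cfg = encoder_cfg
        self.decoder_cfg = decoder_cfg
        self.params = params

    # -- construction --------------------------------------------------------
    @classmethod
    def build(cls, vocab: Vocabulary, schema: PropertySchema,
              residue_cfg: GraphConfig, atom_cfg: GraphConfig,
              encoder_cfg: EncoderConfig, decoder_cfg: DecoderConfig,
              seed: int = 0) -> "GeneratorModel":
        rng = np.random.default_rng(seed)
        if residue_cfg.n_eigenvectors != atom_cfg.n_eigenvectors:
            raise ValueError("views must share n_eigenvectors")
        params = {
            "encoder": init_encoder_params(rng, encoder_cfg,
                                           residue_cfg.n_eigenvectors),
            "embedding": init_embedding_params(rng, schema.size, vocab.size,
                                               encoder_cfg.model_dim),
            "decoder": init_decoder_params(rng, decoder_cfg, vocab.size),
        }
        return cls(vocab, schema, residue_cfg, atom_cfg, encoder_cfg,
                   decoder_cfg, params)

    # -- pocket handling -----------------------------------------------------
    def prepare_pocket(self, pocket: PocketStructure) -> PocketInputs:
        rg = residue_graph(pocket, self.residue_cfg)
        ag = atom_graph(pocket, self.atom_cfg)
        from .pocket_graphs import rbf_encode

        return PocketInputs(
            residue_graph=rg,
            atom_graph=ag,
            residue_positional=laplacian_positional_features(rg, self.residue_cfg),
            atom_positional=laplacian_positional_features(ag, self.atom_cfg),
            residue_edges=rbf_encode(rg.edge_distances, self.residue_cfg),
            atom_edges=rbf_encode(ag.edge_distances, self.atom_cfg),
        )

    def encode(self, inputs: PocketInputs) -> PocketRepresentation:
        return encode_pocket(
            inputs.residue_graph, inputs.atom_graph,
            self.params["encoder"], self.encoder_cfg,
            self.residue_cfg, self.atom_cfg,
            residue_positional=inputs.residue_positional,
            atom_positional=inputs.atom_positional,
            residue_edges=inputs.residue_edges,
            atom_edges=inputs.atom_edges,
        )

    # -- training loss -------------------------------------------------------
    def loss_on_batch(self, items: list[tuple[PocketInputs, MoleculeRecord]],
                      reduction: str = "mean"):
        """Mean NLL over a batch of (pocket, record) pairs.

        Each distinct pocket object is encoded once; pocket representations
        are padded row-wise with a validity mask for the cross-attention.
        """
        if not items:
            raise ValueError("empty batch")
        reps: dict[int, PocketRepresentation] = {}
        for inputs, _ in items:
            if id(inputs) not in reps:
                reps[id(inputs)] = self.encode(inputs)
        per_item = [reps[id(inputs)] for inputs, _ in items]
        p_max = max(r.matrix.shape[0] for r in per_item)
        d = self.encoder_cfg.model_dim
        padded, masks = [], []
        for r in per_item:
            p = r.matrix.shape[0]
            if p < p_max:
                padded.append(T.concatenate(
                    [r.matrix, Tensor(np.zeros((p_max - p, d)))], axis=0))
                masks.append(np.concatenate([r.mask,
                                             np.zeros(p_max - p, dtype=bool)]))
            else:
                padded.append(r.matrix)
                masks.append(r.mask)
        pocket_batch = T.stack(padded, axis=0)
        pocket_mask = np.stack(masks, axis=0)
        seqs = [rec.token_ids for _, rec in items]
        ys = np.stack([rec.y for _, rec in items], axis=0)
        h0, _, _ = embed_molecule_batch(seqs, ys, self.params["embedding"],
                                        self.vocab.pad_id,
                                        max_len=self.decoder_cfg.max_len)
        logits = decoder_forward_batch(h0, pocket_batch, pocket_mask,
                                       self.params["decoder"], self.decoder_cfg)
        targets, mask = build_targets(seqs, h0.shape[1], self.vocab.end_id,
                                      self.vocab.pad_id)
        return nll_loss(logits, targets, mask, reduction=reduction)

    # -- generation ----------------------------------------------------------
    def generate(self, request: GenerationRequest) -> GeneratedSet:
        """Seeded autoregressive top-k sampling, batched over samples."""
        if request.max_len > self.decoder_cfg.max_len:
            raise ValueError("request max_len exceeds the decoder maximum")
        rng = np.random.default_rng(request.seed)
        rep = request.pocket
        y = np.asarray(request.y_desired, dtype=float)
        if y.shape != (self.schema.size,):
            raise ValueError(f"y_desired must have {self.schema.size} entries")
        with T.no_grad():
            pocket_matrix = rep.matrix.data if isinstance(rep.matrix, Tensor) \
                else np.asarray(rep.matrix)
            n = request.n_samples
            tokens: list[list[int]] = [[] for _ in range(n)]
            log_probs = np.zeros(n)
            done = np.zeros(n, dtype=bool)
            termination = ["max_len"] * n
            for _ in range(request.max_len):
                active = np.nonzero(~done)[0]
                if active.size == 0:
                    break
                seqs = [tokens[i] for i in active]
                ys = np.repeat(y[None], active.size, axis=0)
                h0, _, _ = embed_molecule_batch(
                    seqs, ys, self.params["embedding"], self.vocab.pad_id,
                    max_len=self.decoder_cfg.max_len)
                B = active.size
                pocket_batch = Tensor(
                    np.broadcast_to(pocket_matrix[None],
                                    (B, *pocket_matrix.shape)))
                pocket_mask = np.broadcast_to(rep.mask[None],
                                              (B, rep.mask.size))
                logits = decoder_forward_batch(
                    h0, pocket_batch, pocket_mask,
                    self.params["decoder"], self.decoder_cfg).data
                for row, i in enumerate(active):
                    step_logits = logits[row, len(tokens[i]) + 1]
                    tok, lp = sample_next(step_logits, request.top_k,
                                          request.temperature, rng)
                    log_probs[i] += lp
                    if tok == self.vocab.end_id:
                        done[i] = True
                        termination[i] = "end_tag"
                    else:
                        tokens[i].append(tok)
        molecules = []
        for i in range(n):
            smiles = codec.detokenize(tokens[i], self.vocab)
            molecules.append(GeneratedMolecule(
                smiles=smiles, token_ids=list(tokens[i]),
                log_prob=float(log_probs[i]), termination=termination[i]))
        return GeneratedSet(molecules=molecules)

    def generate_beam(self, request: GenerationRequest) -> GeneratedSet:
        """Deterministic beam search with beam width = top_k."""
        rep = request.pocket
        y = np.asarray(request.y_desired, dtype=float)
        with T.no_grad():
            pocket_matrix = rep.matrix.data if isinstance(rep.matrix, Tensor) \
                else np.asarray(rep.matrix)
            beams: list[tuple[list[int], float, str | None]] = [([], 0.0, None)]
            for _ in range(request.max_len):
                candidates = []
                alive = [b for b in beams if b[2] is None]
                if not alive:
                    break
                for seq, lp, _ in alive:
                    h0, _, _ = embed_molecule_batch(
                        [seq], y[None], self.params["embedding"],
                        self.vocab.pad_id, max_len=self.decoder_cfg.max_len)
                    logits = decoder_forward_batch(
                        h0, Tensor(pocket_matrix[None]), rep.mask[None],
                        self.params["decoder"], self.decoder_cfg).data
                    z = logits[0, len(seq) + 1] / request.temperature
                    z = z - z.max()
                    logp = z - np.log(np.exp(z).sum())
                    for tok in np.argsort(-logp)[: request.top_k]:
                        tok = int(tok)
                        if tok == self.vocab.end_id:
                            candidates.append((seq, lp + logp[tok], "end_tag"))
                        else:
                            candidates.append((seq + [tok], lp + logp[tok], None))
                finished = [b for b in beams if b[2] is not None]
                candidates.extend(finished)
                candidates.sort(key=lambda b: -b[1])
                beams = candidates[: request.top_k]
            molecules = [
                GeneratedMolecule(
                    smiles=codec.detokenize(seq, self.vocab),
                    token_ids=list(seq), log_prob=float(lp),
                    termination=term or "max_len")
                for seq, lp, term in beams[: request.n_samples]
            ]
        return GeneratedSet(molecules=molecules)

    # -- checkpointing -------------------------------------------------------
    def flat_params(self) -> dict[str, Tensor]:
        return _flatten_params(self.params)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.flat_params().items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]):
        flat = self.flat_params()
        missing = set(flat) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)[:3]}")
        for name, tensor in flat.items():
            if tensor.data.shape != arrays[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            tensor.data = arrays[name].astype(np.float64).copy()

    def save(self, path: str):
        meta = {
            "version": CHECKPOINT_VERSION,
            "vocab": list(self.vocab.tokens),
            "schema": [asdict(r) for r in self.schema.rules],
            "residue_cfg": asdict(self.residue_cfg),
            "atom_cfg": asdict(self.atom_cfg),
            "encoder_cfg": {**asdict(self.encoder_cfg),
                            "fusion_units": list(self.encoder_cfg.fusion_units)},
            "decoder_cfg": asdict(self.decoder_cfg),
        }
        arrays = {f"param::{k}": v for k, v in self.state_arrays().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "GeneratorModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            vocab = Vocabulary(tokens=tuple(meta["vocab"]))
            rules = []
            for r in meta["schema"]:
                if r.get("standardize") is not None:
                    r = {**r, "standardize": tuple(r["standardize"])}
                rules.append(PropertyRule(**r))
            schema = PropertySchema(rules=tuple(rules))
            enc_meta = dict(meta["encoder_cfg"])
            enc_meta["fusion_units"] = tuple(enc_meta["fusion_units"])
            model = cls.build(
                vocab, schema,
                GraphConfig(**meta["residue_cfg"]),
                GraphConfig(**meta["atom_cfg"]),
                EncoderConfig(**enc_meta),
                DecoderConfig(**meta["decoder_cfg"]),
                seed=0,
            )
            arrays = {k[len("param::"):]: data[k] for k in data.files
                      if k.startswith("param::")}
        model.load_state_arrays(arrays)
        return model
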