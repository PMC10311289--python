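"""SMILES sub-token vocabulary and the joint molecule embedding.

The vocabulary is built by frequency-merging adjacent SMILES syntactic units
(BPE style) until a target number of sub-tokens exists; begin/end tags are
reserved ids 0 and 1 and an internal pad id sits outside the one-hot space.
The molecule embedding sums a property row, token one-hot projections, token
type vectors and sinusoidal positions.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .nn.tensor import Tensor

BEGIN_TOKEN = "<b>"
END_TOKEN = "<e>"

# Atom-level SMILES syntactic units: bracket atoms, two-letter elements,
# single atoms/aromatics, ring-bond digits, bonds and branch punctuation.
_SMILES_UNIT = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|[BCNOPSFIbcnops]|%\d{2}|[0-9]|"
    r"[=#$/\\\.\-\+\(\)])"
)

MAX_SMILES_TOKENS = 200


class TokenizationError(ValueError):
    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


def split_smiles_units(smiles: str) -> list[str]:
    """Split a SMILES string into atomic syntactic units."""
    units: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _SMILES_UNIT.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"unrecognized SMILES syntax at offset {pos}: {smiles[pos:]!r}",
                offset=pos,
            )
        units.append(m.group(0))
        pos = m.end()
    return units


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token list; tags first, then sub-tokens. pad_id is internal."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if self.tokens[:2] != (BEGIN_TOKEN, END_TOKEN):
            raise ValueError("vocabulary must start with the begin/end tags")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def begin_id(self) -> int:
        return 0

    @property
    def end_id(self) -> int:
        return 1

    @property
    def pad_id(self) -> int:
        return len(self.tokens)

    @property
    def size(self) -> int:
        """One-hot/logit dimensionality (pad excluded)."""
        return len(self.tokens)

    @property
    def sub_tokens(self) -> tuple[str, ...]:
        return self.tokens[2:]

    def id_of(self, token: str) -> int:
        return self.tokens.index(token)

    def to_text(self) -> str:
        return "\n".join(self.tokens) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Vocabulary":
        return cls(tokens=tuple(line for line in text.splitlines() if line))


def build_vocabulary(corpus_smiles: list[str], target_size: int = 110) -> Vocabulary:
    """BPE-style vocabulary over SMILES units.

    Starting from the syntactic units present in the corpus, iteratively
    merge the most frequent adjacent pair (ties broken lexicographically)
    until `target_size` sub-tokens exist. Deterministic for a fixed corpus.
    """
    if not corpus_smiles:
        raise ValueError("corpus must contain at least one SMILES string")
    sequences = [split_smiles_units(s) for s in corpus_smiles]
    vocab: list[str] = sorted({u for seq in sequences for u in seq})
    while len(vocab) < target_size:
        pair_counts: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                pair_counts[(a, b)] += 1
        if not pair_counts:
            break
        best = min(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        merged = best[0] + best[1]
        if merged in vocab:
            # already formed via a different split; drop the pair and retry
            new_sequences = []
            for seq in sequences:
                new_seq, i = [], 0
                while i < len(seq):
                    if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                        new_seq.append(merged)
                        i += 2
                    else:
                        new_seq.append(seq[i])
                        i += 1
                new_sequences.append(new_seq)
            sequences = new_sequences
            continue
        vocab.append(merged)
        new_sequences = []
        for seq in sequences:
            new_seq, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                    new_seq.append(merged)
                    i += 2
                else:
                    new_seq.append(seq[i])
                    i += 1
            new_sequences.append(new_seq)
        sequences = new_sequences
    if len(vocab) < target_size:
        warnings.warn(
            f"corpus too small to reach {target_size} sub-tokens; "
            f"stopping at {len(vocab)}"
        )
    return Vocabulary(tokens=(BEGIN_TOKEN, END_TOKEN, *vocab))


def tokenize(smiles: str, vocab: Vocabulary) -> list[int]:
    """Greedy longest-match left-to-right tokenization into sub-token ids."""
    subs = vocab.sub_tokens
    if not subs:
        raise TokenizationError("vocabulary has no sub-tokens")
    by_length = sorted(subs, key=len, reverse=True)
    ids = []
    pos = 0
    while pos < len(smiles):
        for tok in by_length:
            if smiles.startswith(tok, pos):
                ids.append(vocab.id_of(tok))
                pos += len(tok)
                break
        else:
            raise TokenizationError(
                f"no vocabulary token matches {smiles!r} at offset {pos}",
                offset=pos,
            )
    return ids


def detokenize(ids: list[int], vocab: Vocabulary) -> str:
    """Concatenate token strings; begin/end/pad ids are skipped."""
    skip = {vocab.begin_id, vocab.end_id, vocab.pad_id}
    return "".join(vocab.tokens[i] for i in ids if i not in skip)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyRule:
    name: str
    kind: str  # "hard" | "soft"
    threshold: float | None = None
    direction: str | None = None  # "le" -> 1 if value <= threshold; "ge" likewise
    # optional (mean, sd) standardization for soft values; off by default
    standardize: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("hard", "soft"):
            raise ValueError("kind must be 'hard' or 'soft'")
        if self.kind == "hard" and (self.threshold is None or
                                    self.direction not in ("le", "ge")):
            raise ValueError("hard properties need a threshold and direction")
        if self.standardize is not None:
            if self.kind != "soft":
                raise ValueError("only soft properties are standardized")
            if self.standardize[1] <= 0:
                raise ValueError("standardization sd must be positive")


@dataclass(frozen=True)
class PropertySchema:
    rules: tuple[PropertyRule, ...]

    def __post_init__(self):
        if len(self.rules) == 0:
            raise ValueError("schema needs at least one property")

    @property
    def size(self) -> int:
        return len(self.rules)

    def encode(self, values: dict[str, float]) -> np.ndarray:
        """Raw values -> conditioning vector y (hard entries binarized)."""
        y = np.zeros(self.size)
        for i, rule in enumerate(self.rules):
            v = float(values[rule.name])
            if rule.kind == "hard":
                y[i] = binarize_property(v, rule)
            elif rule.standardize is not None:
                mean, sd = rule.standardize
                y[i] = (v - mean) / sd
            else:
                y[i] = v
        return y


def binarize_property(value: float, rule: PropertyRule) -> int:
    """Inclusive thresholding, e.g. docking score <= -7.5 -> 1."""
    if not np.isfinite(value):
        raise ValueError("property value must be finite")
    if rule.kind != "hard":
        raise ValueError("only hard properties are binarized")
    if rule.direction == "le":
        return 1 if value <= rule.threshold else 0
    return 1 if value >= rule.threshold else 0


DOCKING_RULE = PropertyRule(name="affinity", kind="hard",
                            threshold=-7.5, direction="le")
SA_RULE = PropertyRule(name="SA", kind="hard", threshold=4.0, direction="le")
QED_RULE = PropertyRule(name="QED", kind="hard", threshold=0.6, direction="ge")


@dataclass
class MoleculeRecord:
    smiles: str
    token_ids: list[int]
    y: np.ndarray
    docking_score: float

    @classmethod
    def from_smiles(cls, smiles: str, vocab: Vocabulary, schema: PropertySchema,
                    values: dict[str, float], docking_score: float) -> "MoleculeRecord":
        return cls(
            smiles=smiles,
            token_ids=tokenize(smiles, vocab),
            y=schema.encode(values),
            docking_score=docking_score,
        )


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

@dataclass
class MoleculeEmbeddingParams:
    w_prop: Tensor  # (m, d)
    w_token: Tensor  # (vocab_size, d)
    t_prop: Tensor  # (d,) token-type vector for the property tag
    t_word: Tensor  # (d,) token-type vector for everything else


def init_embedding_params(rng: np.random.Generator, n_properties: int,
                          vocab_size: int, d: int) -> MoleculeEmbeddingParams:
    scale = 1.0 / np.sqrt(d)
    return MoleculeEmbeddingParams(
        w_prop=Tensor(rng.normal(0, scale, (n_properties, d)), requires_grad=True),
        w_token=Tensor(rng.normal(0, scale, (vocab_size, d)), requires_grad=True),
        t_prop=Tensor(rng.normal(0, scale, d), requires_grad=True),
        t_word=Tensor(rng.normal(0, scale, d), requires_grad=True),
    )


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    """Classic sine/cosine positional table, wavelengths 2*pi .. r*2*pi."""
    if length < 1 or d < 2:
        raise ValueError("need length >= 1 and d >= 2")
    r = 10000.0
    pos = np.arange(length)[:, None]
    j = np.arange(0, d, 2)[None, :]
    angles = pos / np.power(r, j / d)
    table = np.zeros((length, d))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles[:, : table[:, 1::2].shape[1]])
    return table


def embed_molecule(token_ids: list[int], y: np.ndarray,
                   params: MoleculeEmbeddingParams,
                   max_len: int = MAX_SMILES_TOKENS):
    """Joint embedding h0 of a property-tagged token sequence.

    Row 0 is the property row y @ W_p; rows 1..n+1 embed (begin, a_1..a_n);
    the property row gets type vector t_prop, all others t_word; sinusoidal
    positions are added over all n+2 rows. `token_ids` excludes the tags.
    """
    n = len(token_ids)
    if n + 2 > max_len + 2:
        raise ValueError(f"sequence of {n} tokens exceeds max length {max_len}")
    d = params.w_token.shape[1]
    seq = np.array([0, *token_ids], dtype=np.int64)  # begin tag id = 0
    prop_row = (Tensor(np.asarray(y, dtype=float)) @ params.w_prop).reshape(1, d)
    token_rows = params.w_token[seq]
    from .nn.tensor import concatenate

    h_m = concatenate([prop_row, token_rows], axis=0)
    type_rows = np.zeros((n + 2, 1))
    type_rows[0] = 1.0
    h_type = Tensor(type_rows) * params.t_prop + Tensor(1.0 - type_rows) * params.t_word
    h_pos = Tensor(sinusoidal_positions(n + 2, d))
    return h_m + h_type + h_pos


def embed_molecule_batch(token_id_seqs: list[list[int]], ys: np.ndarray,
                         params: MoleculeEmbeddingParams, pad_id: int,
                         max_len: int = MAX_SMILES_TOKENS):
    """Batched version of :func:`embed_molecule` with right-padding.

    Returns (h0 (B, L, d) Tensor, input_ids (B, L-1) padded with pad_id,
    valid mask (B, L) including the property row).
    """
    B = len(token_id_seqs)
    n_max = max(len(s) for s in token_id_seqs)
    if n_max + 2 > max_len + 2:
        raise ValueError("batch contains a sequence exceeding the max length")
    L = n_max + 2
    d = params.w_token.shape[1]
    ids = np.full((B, L - 1), pad_id, dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    mask[:, 0] = True
    for b, seq in enumerate(token_id_seqs):
        ids[b, 0] = 0
        ids[b, 1 : 1 + len(seq)] = seq
        mask[b, 1 : 2 + len(seq)] = True
    # pad rows use a zero embedding (outside the one-hot space)
    from .nn.tensor import Tensor as Tn
    from .nn.tensor import concatenate

    vocab_size, _ = params.w_token.shape
    safe_ids = np.where(ids == pad_id, 0, ids)
    token_rows = params.w_token[safe_ids] * (ids != pad_id)[..., None].astype(float)
    prop_rows = (Tn(np.asarray(ys, dtype=float)) @ params.w_prop).reshape(B, 1, d)
    h_m = concatenate([prop_rows, token_rows], axis=1)
    type_rows = np.zeros((B, L, 1))
    type_rows[:, 0] = 1.0
    h_type = Tn(type_rows) * params.t_prop + Tn(1.0 - type_rows) * params.t_word
    h_type = h_type * mask[..., None].astype(float)
    h_pos = Tn(sinusoidal_positions(L, d)[None] * mask[..., None].astype(float))
    return h_m + h_type + h_pos, ids, mask
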