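import numpy as np
import pytest

from pockmol.codec import (
    DOCKING_RULE,
    PropertyRule,
    PropertySchema,
    build_vocabulary,
)
from pockmol.decoder import DecoderConfig
from pockmol.encoder import EncoderConfig
from pockmol.fixtures import make_conditioned_corpus
from pockmol.model import GeneratorModel
from pockmol.pocket_graphs import atom_graph_config, residue_graph_config


@pytest.fixture(scope="session")
def small_corpus():
    return make_conditioned_corpus(seed=5, n_records=60)


@pytest.fixture(scope="session")
def char_vocab(small_corpus):
    # C, N, O base units only; no merges at target 3
    return build_vocabulary([e.smiles for e in small_corpus.entries],
                            target_size=3)


@pytest.fixture(scope="session")
def schema():
    return PropertySchema(rules=(
        DOCKING_RULE,
        PropertyRule(name="size", kind="soft"),
    ))


@pytest.fixture
def tiny_configs():
    enc = EncoderConfig(n_units=2, n_heads=2, model_dim=32, key_dim=8,
                        value_dim=16, ffn_dim=64, fusion_units=(1, 2),
                        fusion_heads=2, dropout=0.0)
    dec = DecoderConfig(n_blocks=2, n_heads=2, model_dim=32, key_dim=8,
                        value_dim=16, ffn_dim=64, max_len=40, dropout=0.0)
    return enc, dec


@pytest.fixture
def tiny_model(char_vocab, schema, tiny_configs):
    enc, dec = tiny_configs
    return GeneratorModel.build(
        char_vocab, schema,
        residue_graph_config(n_eigenvectors=4),
        atom_graph_config(n_eigenvectors=4),
        enc, dec, seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
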