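"""Shared fixtures: tiny grammars, tiny networks, genomes on disk.

Everything is generated programmatically and seeded, so the suite needs
no data files.
"""

import numpy as np
import pytest

from peaknet.nn import ArchitectureSpec, Network
from peaknet.sequence import one_hot_encode
from peaknet.synth import GrammarConfig, Motif, _pwm_from_pattern, generate_dataset


@pytest.fixture(scope="session")
def tiny_grammar():
    """A fast 2-cell, 1+1-motif grammar on short sequences."""
    motifs = (
        Motif("ap1", _pwm_from_pattern("TGACTCA"), (0,), 0.5),
        Motif("gc", _pwm_from_pattern("GGGGCGGG"), (1,), 0.5),
    )
    return GrammarConfig(
        n_cells=2, n_sites=800, seq_length=100, motifs=motifs,
        plant_region=(20, 80), label_noise=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_grammar):
    return generate_dataset(tiny_grammar)


@pytest.fixture(scope="session")
def tiny_net_spec():
    # near-global pooling: positional capacity is useless for the tiny
    # grammar and only invites memorization
    return ArchitectureSpec(
        n_targets=2, input_length=100,
        conv_layers=((16, 8, 93),), fc_layers=(16,), dropout_rates=(0.2,),
    )


@pytest.fixture()
def fresh_tiny_net(tiny_net_spec):
    return Network(tiny_net_spec, seed=1)


@pytest.fixture(scope="session")
def trained_tiny(tiny_dataset, tiny_net_spec):
    """A network briefly trained on the tiny grammar (shared, read-only)."""
    from peaknet.peaks import split_dataset
    from peaknet.train import TrainConfig, train

    X = tiny_dataset.encoded()
    Y = tiny_dataset.activity
    split = split_dataset(len(X), test=0.2, valid=0.2, seed=3)
    net = Network(tiny_net_spec, seed=2)
    cfg = TrainConfig(batch_size=32, learning_rate=0.005, patience=15,
                      max_epochs=50, seed=2)
    history = train(net, X, Y, split.train_idx, split.valid_idx, cfg)
    return net, history, split, tiny_dataset


@pytest.fixture()
def indicator_network():
    """A hand-built net whose first filter is a sharp TGACTCA detector."""
    spec = ArchitectureSpec(
        n_targets=1, input_length=60,
        conv_layers=((2, 7, 3),), fc_layers=(4,), dropout_rates=(0.0,),
    )
    net = Network(spec, seed=0, dtype=np.float64)
    conv = net.layers[0]
    conv.W[...] = 0.0
    conv.W[0] = 10.0 * (one_hot_encode("TGACTCA", dtype=np.float64) - 0.5)
    conv.b[...] = 0.0
    # make conv batch norm the identity so activations stay interpretable
    bn = net.layers[1]
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
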