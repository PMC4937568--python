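import math

import numpy as np
import pytest

from peaknet.nn import (ArchitectureSpec, Network, bce_loss, convolve,
                        max_pool, relu)
from peaknet.sequence import one_hot_encode


# ---------------------------------------------------------------------------
# convolution


def indicator_filter(motif):
    f = np.zeros((1, 4, len(motif)))
    for i, b in enumerate(motif):
        f[0, "ACGT".index(b), i] = 1.0
    return f


def brute_force_convolve(filters, x):
    F, C, W = filters.shape
    P = x.shape[1] - W + 1
    out = np.zeros((F, P))
    for f in range(F):
        for p in range(P):
            for c in range(C):
                for w in range(W):
                    out[f, p] += filters[f, c, w] * x[c, p + w]
    return out


def test_convolve_indicator_counts_matches():
    acts = convolve(indicator_filter("TGA"), one_hot_encode("CCTGACC"))
    np.testing.assert_allclose(acts, [[0, 0, 3, 0, 0]])


def test_convolve_zero_filter():
    acts = convolve(np.zeros((1, 4, 3)), one_hot_encode("ACGTACG"))
    np.testing.assert_allclose(acts, 0.0)


def test_convolve_single_position_filter():
    f = np.zeros((1, 4, 1))
    f[0, 0, 0] = 1.0  # A detector
    np.testing.assert_allclose(convolve(f, one_hot_encode("AAC")), [[1, 1, 0]])


def test_convolve_rejects_short_input():
    with pytest.raises(ValueError):
        convolve(np.zeros((1, 4, 5)), one_hot_encode("ACG"))


@pytest.mark.parametrize("trial", range(5))
def test_convolve_matches_brute_force(trial):
    rng = np.random.default_rng(trial)
    filters = rng.normal(size=(3, 4, 4))
    x = rng.random((4, 12))
    np.testing.assert_allclose(convolve(filters, x),
                               brute_force_convolve(filters, x), atol=1e-10)


# ---------------------------------------------------------------------------
# relu / pooling / loss


def test_relu():
    np.testing.assert_array_equal(relu(np.array([-2.0, 0.0, 3.0])), [0, 0, 3])
    x = np.random.default_rng(0).normal(size=20)
    np.testing.assert_array_equal(relu(relu(x)), relu(x))
    assert relu(np.array([-5.0, -1.0])).max() == 0


def test_max_pool():
    np.testing.assert_array_equal(max_pool([1, 5, 2, 4], 2), [5, 4])
    np.testing.assert_array_equal(max_pool([1, 5, 2, 4], 1), [1, 5, 2, 4])
    np.testing.assert_array_equal(max_pool([1, 5, 2], 2), [5, 2])  # trailing kept


def test_bce_closed_forms():
    T = 7
    pred = np.full((3, T), 0.5)
    target = (np.random.default_rng(0).random((3, T)) < 0.4).astype(float)
    assert bce_loss(pred, target) == pytest.approx(T * math.log(2), rel=1e-12)
    # predictions approaching the target drive the loss to zero
    eps_pred = np.where(target == 1, 1 - 1e-9, 1e-9)
    assert bce_loss(eps_pred, target) == pytest.approx(0.0, abs=1e-6)
    # hand arithmetic: B=1, T=2
    val = bce_loss(np.array([[0.9, 0.2]]), np.array([[1.0, 0.0]]))
    assert val == pytest.approx(-(math.log(0.9) + math.log(0.8)), rel=1e-12)


# ---------------------------------------------------------------------------
# architecture validation


def test_architecture_rejects_overconsuming_stack():
    with pytest.raises(ValueError):
        ArchitectureSpec(n_targets=1, input_length=10,
                         conv_layers=((4, 8, 2), (4, 8, 2)),
                         fc_layers=(4,), dropout_rates=(0.0,))


def test_architecture_rejects_zero_targets():
    with pytest.raises(ValueError):
        ArchitectureSpec(n_targets=0, input_length=100)


# ---------------------------------------------------------------------------
# full forward pass


def _tiny_net():
    spec = ArchitectureSpec(n_targets=1, input_length=6,
                            conv_layers=((1, 3, 2),), fc_layers=(1,),
                            dropout_rates=(0.0,))
    return Network(spec, seed=0, dtype=np.float64)


def test_forward_matches_hand_computed_composition():
    """Five-stage composition (conv, bn, relu, pool, fc) against an
    independent scalar-arithmetic oracle in eval mode."""
    net = _tiny_net()
    conv, bn1 = net.layers[0], net.layers[1]
    fc, bn2, final = net.layers[5], net.layers[6], net.layers[9]

    conv.W[0] = [[0.5, -0.25, 0.125], [1.0, 0.0, -0.5],
                 [0.25, 0.75, -1.0], [-0.125, 0.5, 0.25]]
    conv.b[:] = 0.1
    bn1.gamma[:] = 1.3
    bn1.beta[:] = 0.2
    bn1.running_mean[:] = 0.1
    bn1.running_var[:] = 0.5
    fc.W[:] = [[0.8, -0.6]]
    fc.b[:] = -0.05
    bn2.gamma[:] = 0.9
    bn2.beta[:] = -0.1
    bn2.running_mean[:] = 0.05
    bn2.running_var[:] = 2.0
    final.W[:] = [[1.7]]
    final.b[:] = 0.3

    seq = "ACGTGA"
    x = one_hot_encode(seq, dtype=np.float64)

    # --- oracle: explicit scalar arithmetic over the stated definitions ---
    W = np.array(conv.W[0])
    acts = []
    for p in range(4):  # 6 - 3 + 1 valid offsets
        s = 0.1
        for c in range(4):
            for w in range(3):
                s += W[c, w] * x[c, p + w]
        acts.append(s)
    bn = [((a - 0.1) / math.sqrt(0.5 + 1e-5)) * 1.3 + 0.2 for a in acts]
    rl = [max(a, 0.0) for a in bn]
    pooled = [max(rl[0], rl[1]), max(rl[2], rl[3])]
    h = 0.8 * pooled[0] - 0.6 * pooled[1] - 0.05
    h = ((h - 0.05) / math.sqrt(2.0 + 1e-5)) * 0.9 - 0.1
    h = max(h, 0.0)
    z = 1.7 * h + 0.3
    expected = 1.0 / (1.0 + math.exp(-z))

    got = net.forward(x[None])[0, 0]
    assert got == pytest.approx(expected, abs=1e-6)


def test_zero_final_layer_gives_half():
    net = _tiny_net()
    net.final.W[...] = 0.0
    net.final.b[...] = 0.0
    x = one_hot_encode("ACGTGA", dtype=np.float64)
    assert net.forward(x[None])[0, 0] == pytest.approx(0.5)


def test_eval_forward_deterministic_and_interior():
    spec = ArchitectureSpec(n_targets=3, input_length=30,
                            conv_layers=((4, 5, 2),), fc_layers=(6,),
                            dropout_rates=(0.5,))
    net = Network(spec, seed=4)
    X = np.random.default_rng(1).random((5, 4, 30)).astype(np.float32)
    p1 = net.forward(X)
    p2 = net.forward(X)
    np.testing.assert_array_equal(p1, p2)
    assert np.all((p1 > 0) & (p1 < 1))


def test_forward_rejects_wrong_length():
    net = _tiny_net()
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 4, 7)))


def test_final_bias_monotonicity():
    net = _tiny_net()
    x = one_hot_encode("ACGTGA", dtype=np.float64)[None]
    before = net.forward(x)[0, 0]
    net.final.b[0] += 0.5
    assert net.forward(x)[0, 0] > before


# ---------------------------------------------------------------------------
# gradients


def test_backprop_matches_finite_differences():
    spec = ArchitectureSpec(n_targets=2, input_length=12,
                            conv_layers=((3, 3, 2), (2, 2, 2)),
                            fc_layers=(4,), dropout_rates=(0.0,))
    net = Network(spec, seed=3, dtype=np.float64)
    rng = np.random.default_rng(5)
    X = rng.random((4, 4, 12))
    Y = (rng.random((4, 2)) < 0.5).astype(float)

    def train_mode_loss():
        state = net.get_state()  # forward updates running moments; restore
        z = net.forward_logits(X, train=True)
        loss = float((np.logaddexp(0, z) - Y * z).sum(axis=1).mean())
        net.set_state(state)
        return loss

    _, grads = net.loss_and_grads(X, Y)
    eps = 1e-6
    for pi, (p, g) in enumerate(zip(net.parameters(), grads)):
        sample = np.random.default_rng(pi).choice(
            p.size, size=min(p.size, 8), replace=False)
        for fi in sample:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = train_mode_loss()
            p[idx] = orig - eps
            lm = train_mode_loss()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            # relative 1e-4 with an absolute floor for analytically-zero
            # gradients (biases cancelled by the following batch norm)
            assert abs(fd - g[idx]) <= max(1e-4 * max(abs(fd), abs(g[idx])), 1e-7)


def test_translation_quasi_invariance():
    """Shifting a planted motif by less than the pool width changes the
    pooled detector output in at most two windows."""
    motif = "TGACTCA"
    filt = np.where(indicator_filter(motif) > 0, 1.0, -10.0)
    pool = 3

    def pooled_map(pos):
        seq = "A" * pos + motif + "A" * (40 - pos - len(motif))
        return max_pool(relu(convolve(filt, one_hot_encode(seq))[0]), pool)

    base = pooled_map(12)
    for shift in (1, 2):
        moved = pooled_map(12 + shift)
        assert np.sum(base != moved) <= 2


def test_nullify_all_filters_makes_predictions_constant():
    spec = ArchitectureSpec(n_targets=2, input_length=30,
                            conv_layers=((4, 5, 2),), fc_layers=(6,),
                            dropout_rates=(0.0,))
    net = Network(spec, seed=9)
    X = np.random.default_rng(3).random((6, 4, 30)).astype(np.float32)
    preds = net.forward(X, conv1_replace={f: 0.37 for f in range(4)})
    np.testing.assert_allclose(preds, np.broadcast_to(preds[0], preds.shape),
                               atol=1e-6)


def test_reverse_complement_averaging_is_symmetric():
    """With rc_average the prediction for a sequence equals that for its
    reverse complement."""
    from peaknet.sequence import one_hot_encode, reverse_complement

    spec = ArchitectureSpec(n_targets=2, input_length=30,
                            conv_layers=((4, 5, 2),), fc_layers=(6,),
                            dropout_rates=(0.0,))
    net = Network(spec, seed=12, dtype=np.float64)
    seq = "ACGTTGCAATCGGATCCATGGCAATTGCAC"
    x = one_hot_encode(seq, dtype=np.float64)[None]
    x_rc = one_hot_encode(reverse_complement(seq), dtype=np.float64)[None]
    np.testing.assert_allclose(net.predict(x, rc_average=True),
                               net.predict(x_rc, rc_average=True), atol=1e-12)
    # one-hot reverse complement used internally matches the string route
    np.testing.assert_allclose(x[:, ::-1, ::-1], x_rc)
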