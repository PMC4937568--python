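"""Model interpretation: filter -> PWM distillation, influence, probing.

A first-layer convolution filter is summarized as a position weight
matrix by scanning it over a sequence set, collecting every window that
activates it to more than half its global maximum and counting
nucleotide occurrences position-wise (plus a small pseudocount).  The
information content of the resulting PWM m against background b is

    IC = sum_i [ -sum_j b_j log2 b_j + sum_j m_ij log2 m_ij ]

i.e. background entropy minus motif entropy, accumulated per position.

A filter's influence is measured by nullification: its post-ReLU
activation map is replaced everywhere by one scalar — the filter's mean
activation over all positions of the test sequences — which blocks any
information (including positional) from passing through it.  The
influence score is the sum of squares over cell types of the change in
mean predicted accessibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class DeadFilterError(ValueError):
    """The filter never activates above zero on the given sequences."""


@dataclass
class FilterPWM:
    filter_id: int
    matrix: np.ndarray        # (W, 4), rows sum to 1
    background: np.ndarray    # (4,)
    ic: float                 # bits
    n_supporting: int         # windows above half-max activation

    @property
    def width(self):
        return self.matrix.shape[0]

    @property
    def consensus(self):
        from .sequence import BASES

        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class InfluenceProfile:
    filter_id: int
    per_cell_delta: np.ndarray  # (T,)
    influence: float            # sum of squares of per_cell_delta


def information_content(m, b=None) -> float:
    """Bits of PWM ``m`` (rows sum to 1) relative to background ``b``.

    The background entropy term is added once per motif position;
    0*log2(0) is taken as 0.
    """
    m = np.asarray(m, dtype=float)
    b = np.full(4, 0.25) if b is None else np.asarray(b, dtype=float)
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM rows must sum to 1")
    if not np.isclose(b.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")

    def xlog2x(p):
        out = np.zeros_like(p)
        nz = p > 0
        out[nz] = p[nz] * np.log2(p[nz])
        return out

    W = m.shape[0]
    return float(-W * xlog2x(b).sum() + xlog2x(m).sum())


def filter_to_pwm(network, filter_id, X, pseudocount=1.0, background=None,
                  batch_size=256) -> FilterPWM:
    """Distill one first-layer filter into a PWM by half-max counting.

    Scans the filter over all of ``X`` (post-ReLU activations), collects
    every filter-width window whose activation exceeds half the filter's
    maximum over the whole set, and counts nucleotides position-wise;
    ``pseudocount`` is the total count added per position (0.25 per
    nucleotide by default).  Raises :class:`DeadFilterError` when the
    filter's maximum activation is not positive.
    """
    X = np.asarray(X)
    W = network.spec.conv_layers[0][1]
    acts = network.conv1_activations(X, batch_size=batch_size)[:, filter_id, :]
    max_act = float(acts.max())
    if max_act <= 0:
        raise DeadFilterError(f"filter {filter_id} never activates above zero")
    hits = np.argwhere(acts > max_act / 2.0)
    counts = np.zeros((W, 4))
    for b, p in hits:
        counts += X[b, :, p : p + W].T
    n = len(hits)
    matrix = (counts + pseudocount / 4.0) / (n + pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return FilterPWM(
        filter_id=int(filter_id),
        matrix=matrix,
        background=bg,
        ic=information_content(matrix, bg),
        n_supporting=n,
    )


def all_filter_pwms(network, X, **kwargs):
    """PWMs for every first-layer filter; dead filters are skipped (logged)."""
    n_filters = network.spec.conv_layers[0][0]
    pwms = []
    for f in range(n_filters):
        try:
            pwms.append(filter_to_pwm(network, f, X, **kwargs))
        except DeadFilterError:
            logger.info("filter %d is dead on this sequence set", f)
    return pwms


def filter_influence(network, X, batch_size=256):
    """Nullification influence of every first-layer filter on ``X``."""
    X = np.asarray(X)
    orig_mean = network.predict(X, batch_size=batch_size).mean(axis=0)
    acts = network.conv1_activations(X, batch_size=batch_size)
    n_filters = network.spec.conv_layers[0][0]
    profiles = []
    for f in range(n_filters):
        const = float(acts[:, f, :].mean())
        nulled = network.predict(X, batch_size=batch_size, conv1_replace={f: const})
        delta = orig_mean - nulled.mean(axis=0)
        profiles.append(
            InfluenceProfile(f, delta, float(np.square(delta).sum()))
        )
    return profiles


def motif_insertion_effect(network, motif, X, sample=False, rng=None):
    """Prediction change from inserting ``motif`` at the center of each sequence.

    ``motif`` is a consensus string or a (W, 4) PWM; with ``sample=True``
    a fresh PWM sample is drawn per sequence, otherwise the consensus is
    inserted.  Returns pred(after) - pred(before), shape (N, T).
    """
    from .sequence import BASES, one_hot_encode

    X = np.asarray(X)
    L = X.shape[2]
    if isinstance(motif, str):
        pwm = None
        W = len(motif)
        block = one_hot_encode(motif, dtype=X.dtype)
    else:
        pwm = np.asarray(motif, dtype=float)
        W = pwm.shape[0]
        consensus = "".join(BASES[i] for i in pwm.argmax(axis=1))
        block = one_hot_encode(consensus, dtype=X.dtype)
    if W > L:
        raise ValueError("motif wider than the sequence")
    start = (L - W) // 2
    before = network.predict(X)
    Xm = X.copy()
    if sample:
        if pwm is None:
            raise ValueError("sampling requires a PWM, not a consensus string")
        rng = rng or np.random.default_rng()
        eye = np.eye(4, dtype=X.dtype)
        for i in range(len(Xm)):
            draw = np.array([rng.choice(4, p=row) for row in pwm])
            Xm[i, :, start : start + W] = eye[draw].T
    else:
        Xm[:, :, start : start + W] = block
    after = network.predict(Xm)
    return after - before


def cluster_influence(profiles):
    """Average-linkage hierarchical clustering of per-cell influence vectors.

    Returns (linkage_matrix, leaf_order) using Euclidean distance.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    mat = np.stack([p.per_cell_delta for p in profiles])
    Z = linkage(mat, method="average", metric="euclidean")
    return Z, leaves_list(Z)


def write_meme(pwms, path, background=None):
    """Write PWMs in MEME minimal motif format (for e.g. TomTom search)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF filter_{pwm.filter_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {pwm.n_supporting} E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def influence_table(profiles, cell_names=None):
    import pandas as pd

    T = len(profiles[0].per_cell_delta) if profiles else 0
    names = list(cell_names) if cell_names is not None else [f"cell_{t}" for t in range(T)]
    rows = []
    for p in profiles:
        row = {"filter": p.filter_id, "influence": p.influence}
        row.update({f"delta_{n}": d for n, d in zip(names, p.per_cell_delta)})
        rows.append(row)
    return pd.DataFrame(rows)
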