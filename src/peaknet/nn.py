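"""Multi-task convolutional network over one-hot DNA, in plain NumPy.

The model maps a 4 x L one-hot sequence to T probabilities of chromatin
accessibility, one per cell type.  Each convolution stage is a valid
(unpadded) cross-correlation followed by batch normalization, a ReLU and
non-overlapping max-pooling; the pooled maps are flattened and passed
through fully connected stages (linear -> batchnorm -> ReLU -> dropout)
and a final linear map to T logits squashed by a sigmoid.  Training
minimizes binary cross entropy summed over the T targets and averaged
over the minibatch.

Everything needed for gradient-based training is implemented here:
forward passes cache intermediates and ``backward`` consumes them, so a
``Network`` can hand an optimizer exact gradients for every parameter,
including batch-normalization scale/shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer hyperparameters of the accessibility CNN.

    Parameters
    ----------
    n_targets : int
        Number of cell types T predicted by the final layer.
    input_length : int
        Sequence length in bp the network accepts.
    conv_layers : tuple of (n_filters, filter_width, pool_width)
        One tuple per convolution stage.
    fc_layers : tuple of int
        Hidden-unit counts of the fully connected stages.
    dropout_rates : tuple of float
        Dropout probability applied after each fully connected stage.
    """

    n_targets: int
    input_length: int = 600
    conv_layers: tuple = ((300, 19, 3), (200, 11, 4), (200, 7, 4))
    fc_layers: tuple = (1000, 1000)
    dropout_rates: tuple = (0.3, 0.3)

    def __post_init__(self):
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if len(self.conv_layers) < 1:
            raise ValueError("at least one convolution layer is required")
        if len(self.dropout_rates) != len(self.fc_layers):
            raise ValueError("need one dropout rate per fully connected layer")
        for nf, fw, pw in self.conv_layers:
            if min(nf, fw, pw) < 1:
                raise ValueError("conv layer sizes must be >= 1")
        if self.spatial_extent() < 1:
            raise ValueError("conv/pool stack consumes the whole sequence")

    def spatial_extent(self) -> int:
        """Positions per filter after the last conv/pool stage."""
        length = self.input_length
        for _, fw, pw in self.conv_layers:
            length = length - fw + 1
            if length < 1:
                return length
            length = -(-length // pw)  # trailing partial window kept
        return length

    def flat_features(self) -> int:
        return self.conv_layers[-1][0] * self.spatial_extent()


def default_architecture(n_targets: int, input_length: int = 600) -> ArchitectureSpec:
    """The full-scale three-conv-stage architecture."""
    return ArchitectureSpec(n_targets=n_targets, input_length=input_length)


def small_architecture(n_targets: int, input_length: int = 600) -> ArchitectureSpec:
    """A two-conv-stage architecture (50 + 50 filters) for desk-scale data.

    The second stage pools globally: with ~1e4 training sites a
    positional flatten invites pure memorization of one-hot inputs,
    whereas presence/combination codes survive global pooling.
    """
    extent = (input_length - 19 + 1) // 4 - 7 + 1
    return ArchitectureSpec(
        n_targets=n_targets,
        input_length=input_length,
        conv_layers=((50, 19, 4), (50, 7, max(extent, 1))),
        fc_layers=(64,),
        dropout_rates=(0.3,),
    )


# ---------------------------------------------------------------------------
# layers


class Conv1D:
    """Valid cross-correlation of F filters (shape C x W) over channels-last
    input (B, L, C); output is (B, L-W+1, F).

    Channels-last makes the im2col matrix a contiguous-stride view of the
    input (each window row overlaps the previous, shifted by C), so the
    only large copies are sequential and cache-friendly.
    """

    def __init__(self, c_in, n_filters, width, rng, dtype):
        self.c_in, self.n_filters, self.width = c_in, n_filters, width
        fan_in = c_in * width
        # logical layout (F, C, W): filter f, channel c, offset w
        self.W = rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                            (n_filters, c_in, width)).astype(dtype)
        self.b = np.zeros(n_filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _wmat(self):
        # (W*C, F) with rows laid out (offset, channel) to match im2col
        return np.ascontiguousarray(self.W.transpose(2, 1, 0)).reshape(
            self.width * self.c_in, self.n_filters)

    def forward(self, x, train=False):
        B, L, C = x.shape
        if L < self.width:
            raise ValueError(f"input length {L} shorter than filter width {self.width}")
        P = L - self.width + 1
        itemsize = x.itemsize
        sB, sL, _ = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, shape=(B, P, self.width * C), strides=(sB, sL, itemsize))
        cols = np.ascontiguousarray(cols).reshape(B * P, self.width * C)
        out = (cols @ self._wmat() + self.b).reshape(B, P, self.n_filters)
        if train:
            self._cache = (cols, (B, C, L, P))
        return out

    def backward(self, dout):
        cols, (B, C, L, P) = self._cache
        d2 = dout.reshape(B * P, self.n_filters)
        dwmat = cols.T @ d2  # (W*C, F)
        self.dW[...] = dwmat.reshape(self.width, C, self.n_filters).transpose(2, 1, 0)
        self.db[...] = d2.sum(axis=0)
        dcols = (d2 @ self._wmat().T).reshape(B, P, self.width, C)
        dx = np.zeros((B, L, C), dtype=dout.dtype)
        for w in range(self.width):
            dx[:, w : w + P, :] += dcols[:, :, w, :]
        return dx

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm:
    """Batch normalization over (batch,) or (batch, positions) per feature.

    Training mode normalizes with minibatch statistics and maintains an
    exponential moving average of the moments (momentum 0.9); eval mode
    applies the running moments, making the layer a fixed affine map.
    """

    def __init__(self, n_features, spatial, dtype, momentum=0.9, eps=1e-5):
        self.spatial = spatial  # True for conv maps (B, P, F)
        self.momentum, self.eps = momentum, eps
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x, train=False):
        # features on the last axis; stats pool batch (and positions if spatial)
        axes = (0, 1) if self.spatial else (0,)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if train:
            self._cache = (xhat, inv_std, x - mu)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std, xc = self._cache
        axes = (0, 1) if self.spatial else (0,)
        n = dout.shape[0] * (dout.shape[1] if self.spatial else 1)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        # backprop through the batch statistics
        dvar = (dxhat * xc).sum(axis=axes) * (-0.5) * inv_std**3
        dmu = -dxhat.sum(axes) * inv_std + dvar * (-2.0 / n) * xc.sum(axes)
        return dxhat * inv_std + (2.0 / n) * dvar * xc + dmu / n

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


def relu(x):
    """Elementwise max(x, 0)."""
    return np.maximum(x, 0)


class MaxPool1D:
    """Non-overlapping max pooling along the last axis; a trailing partial
    window is kept (max of the remainder)."""

    def __init__(self, pool_width):
        if pool_width < 1:
            raise ValueError("pool_width must be >= 1")
        self.pool_width = pool_width
        self._cache = None

    def forward(self, x, train=False):
        B, P, F = x.shape
        k = self.pool_width
        n_out = -(-P // k)
        pad = n_out * k - P
        if pad:
            xp = np.concatenate(
                [x, np.full((B, pad, F), -np.inf, dtype=x.dtype)], axis=1
            )
        else:
            xp = x
        xr = xp.reshape(B, n_out, k, F)
        arg = xr.argmax(axis=2)
        out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache = (arg, (B, P, F, n_out, k))
        return out

    def backward(self, dout):
        arg, (B, P, F, n_out, k) = self._cache
        dxp = np.zeros((B, n_out, k, F), dtype=dout.dtype)
        np.put_along_axis(dxp, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        return dxp.reshape(B, n_out * k, F)[:, :P, :]

    def params(self):
        return []


def max_pool(x, pool_width):
    """Functional max pooling over the last axis (any leading shape)."""
    arr = np.asarray(x, dtype=float)
    lead = arr.shape[:-1]
    flat = arr.reshape(int(np.prod(lead)) if lead else 1, arr.shape[-1], 1)
    out = MaxPool1D(pool_width).forward(flat)[:, :, 0]
    return out.reshape(*lead, out.shape[-1]) if lead else out[0]


class Flatten:
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in, n_out, rng, dtype):
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


def convolve(filters, x):
    """Valid cross-correlation of filters (F, 4, W) against one-hot input.

    ``x`` may be a single (4, L) matrix or a batch (B, 4, L); returns
    activations of shape (F, L-W+1) or (B, F, L-W+1).  Output column p is
    the elementwise product-sum of each filter with the 4 x W window
    starting at p (no padding).
    """
    filters = np.asarray(filters, dtype=float)
    arr = np.asarray(x, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    F, C, W = filters.shape
    if arr.shape[2] < W:
        raise ValueError("input shorter than filter width")
    win = sliding_window_view(arr, W, axis=2)  # (B, C, P, W)
    out = np.einsum("bcpw,fcw->bfp", win, filters)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# losses


def bce_loss(pred, target, eps=1e-7):
    """Binary cross entropy, summed over targets, averaged over the batch.

    ``pred`` should lie strictly in (0, 1); natural logarithm.  Values
    are clipped to [eps, 1-eps] because a float32 sigmoid can round to
    exactly 0 or 1.
    """
    pred = np.clip(np.asarray(pred, dtype=float), eps, 1.0 - eps)
    target = np.asarray(target, dtype=float)
    per_seq = -(target * np.log(pred) + (1 - target) * np.log1p(-pred)).sum(axis=-1)
    return float(np.mean(per_seq))


def _bce_from_logits(z, y):
    # log(1 + e^z) - y z, numerically stable
    per = np.logaddexp(0.0, z) - y * z
    return float(per.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# network


class Network:
    """The accessibility CNN: parameters, forward pass and backprop.

    Parameters are initialized from ``seed``; dropout draws from the same
    generator, so a freshly built network trained with a seeded loop is
    fully reproducible.  ``dtype`` defaults to float32 for speed; use
    float64 when checking gradients.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.rng = np.random.default_rng(seed)
        self.layers = []
        self._conv1_relu_index = None

        c_in = 4
        for i, (nf, fw, pw) in enumerate(spec.conv_layers):
            self.layers.append(Conv1D(c_in, nf, fw, self.rng, dtype))
            self.layers.append(BatchNorm(nf, spatial=True, dtype=dtype))
            self.layers.append(ReLU())
            if i == 0:
                self._conv1_relu_index = len(self.layers) - 1
            self.layers.append(MaxPool1D(pw))
            c_in = nf
        self.layers.append(Flatten())
        n_in = spec.flat_features()
        for units, rate in zip(spec.fc_layers, spec.dropout_rates):
            self.layers.append(Dense(n_in, units, self.rng, dtype))
            self.layers.append(BatchNorm(units, spatial=False, dtype=dtype))
            self.layers.append(ReLU())
            self.layers.append(Dropout(rate, self.rng))
            n_in = units
        self.final = Dense(n_in, spec.n_targets, self.rng, dtype)
        self.layers.append(self.final)

    # -- forward -----------------------------------------------------------

    def _check_input(self, x):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != 4 or x.shape[2] != self.spec.input_length:
            raise ValueError(
                f"expected input shape (B, 4, {self.spec.input_length}), got {x.shape}"
            )
        # channels-last internally
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def forward_logits(self, x, train=False, conv1_replace=None):
        x = self._check_input(x)
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if i == self._conv1_relu_index and conv1_replace is not None:
                x = np.array(x, copy=True)
                for f, value in conv1_replace.items():
                    x[:, :, f] = value
        return x

    def forward(self, x, train=False, conv1_replace=None):
        """Per-cell accessibility probabilities, shape (B, T)."""
        return expit(self.forward_logits(x, train=train, conv1_replace=conv1_replace))

    def predict(self, x, batch_size=256, conv1_replace=None, rc_average=False):
        """Eval-mode probabilities computed in minibatches.

        ``rc_average=True`` averages predictions over the sequence and
        its reverse complement (off by default: the model is
        single-strand).
        """
        x = np.asarray(x)
        out = []
        for lo in range(0, len(x), batch_size):
            xb = x[lo : lo + batch_size]
            p = self.forward(xb, conv1_replace=conv1_replace)
            if rc_average:
                p = 0.5 * (p + self.forward(xb[:, ::-1, ::-1],
                                            conv1_replace=conv1_replace))
            out.append(p)
        return np.concatenate(out, axis=0)

    def conv1_activations(self, x, batch_size=256):
        """Post-ReLU first-stage activation maps, shape (B, F, P)."""
        x = np.asarray(x)
        conv, bn, act = self.layers[0], self.layers[1], self.layers[2]
        out = []
        for lo in range(0, len(x), batch_size):
            xb = self._check_input(x[lo : lo + batch_size])
            a = act.forward(bn.forward(conv.forward(xb)))  # (B, P, F)
            out.append(np.ascontiguousarray(a.transpose(0, 2, 1)))
        return np.concatenate(out, axis=0)

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, x, y):
        """BCE loss on a minibatch plus gradients for every parameter.

        Runs a train-mode forward pass (batch statistics, dropout) and a
        full backward pass; gradients are stored on the layers and also
        returned aligned with :meth:`parameters`.
        """
        y = np.asarray(y, dtype=self.dtype)
        z = self.forward_logits(x, train=True)
        loss = _bce_from_logits(z, y)
        dz = ((expit(z) - y) / z.shape[0]).astype(self.dtype)
        grad = dz
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, self.gradients()

    def eval_loss(self, x, y, batch_size=256):
        p = self.predict(x, batch_size=batch_size)
        return bce_loss(p, y)

    def parameters(self):
        """Live parameter arrays (updated in place by an optimizer)."""
        return [p for layer in self.layers for _, p, _ in layer.params()]

    def gradients(self):
        return [g for layer in self.layers for _, _, g in layer.params()]

    # -- state -------------------------------------------------------------

    def get_state(self):
        """Deep-copied parameter and running-moment state, keyed by layer."""
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p, _ in layer.params():
                state[f"layer{i:03d}/{name}"] = p.copy()
            if isinstance(layer, BatchNorm):
                state[f"layer{i:03d}/running_mean"] = layer.running_mean.copy()
                state[f"layer{i:03d}/running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state):
        for i, layer in enumerate(self.layers):
            for name, p, _ in layer.params():
                p[...] = state[f"layer{i:03d}/{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i:03d}/running_mean"]
                layer.running_var[...] = state[f"layer{i:03d}/running_var"]

    def copy(self):
        new = Network(self.spec, seed=0, dtype=self.dtype)
        new.set_state(self.get_state())
        return new
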