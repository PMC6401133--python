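"""Minimal CPU neural-network engine for the residual contact networks.

Implements exactly what the package's two models need: stride-1 "same"
convolutions (2D for the contact network, 1D via a 1 x k kernel for the
secondary-structure network) with im2col/matmul forward passes and
analytically derived backward passes, ReLU, residual additions, a
transpose-averaging symmetrisation layer, per-pixel softmax cross-entropy
with class weights and an ignore mask, and momentum SGD with L2 weight
decay.  Everything is deterministic given the RNG handed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C, H, W) -> (H*W, C*kh*kw) patches with zero 'same' padding."""
    C, H, W = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (C, H, W, kh, kw)
    return np.ascontiguousarray(
        win.transpose(1, 2, 0, 3, 4).reshape(H * W, C * kh * kw)
    )


class Conv:
    """Stride-1 zero-padded convolution with a (kh, kw) kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        fan_in = c_in * self.kh * self.kw
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(fan_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._vW = np.zeros_like(self.W)
        self._vb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        _, H, W = x.shape
        cols = _im2col(x, self.kh, self.kw)
        if train:
            self._cols, self._shape = cols, (H, W)
        out = cols @ self.W + self.b
        return out.T.reshape(self.c_out, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called without a train-mode forward")
        H, W = self._shape
        dflat = dout.reshape(self.c_out, H * W).T
        self.dW += self._cols.T @ dflat
        self.db += dflat.sum(axis=0)
        # gradient w.r.t. input: convolve dout with the flipped kernels
        W4 = self.W.reshape(self.c_in, self.kh, self.kw, self.c_out)
        Wback = np.ascontiguousarray(
            W4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
                self.c_out * self.kh * self.kw, self.c_in
            )
        )
        cols_d = _im2col(dout, self.kh, self.kw)
        dx = (cols_d @ Wback).T.reshape(self.c_in, H, W)
        self._cols = None
        return dx

    def zero_grad(self) -> None:
        self.dW.fill(0.0)
        self.db.fill(0.0)

    def sgd_step(self, lr: float, momentum: float, weight_decay: float) -> None:
        self._vW = momentum * self._vW - lr * (self.dW + weight_decay * self.W)
        self._vb = momentum * self._vb - lr * self.db
        self.W += self._vW
        self.b += self._vb


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sym(a: np.ndarray) -> np.ndarray:
    """Average a (C, L, L) stack with its spatial transpose."""
    return (a + a.transpose(0, 2, 1)) / 2.0


class ResidualCNN:
    """Fully convolutional residual network with optional symmetrised output.

    entry conv -> ReLU -> ``n_blocks`` residual blocks (conv, ReLU, conv,
    add skip, ReLU) -> [transpose-average] -> final conv to ``c_out``
    channels -> [transpose-average of the logits] -> per-position softmax.

    With ``symmetrize=True`` (the contact network) the transpose-averaging
    makes the class probabilities bitwise symmetric in (i, j).  The
    secondary-structure variant runs the same machinery on (C, 1, L) inputs
    with a 1 x k kernel and ``symmetrize=False``.  No batch normalisation
    and no dropout, so any input length is accepted.
    """

    def __init__(self, c_in: int, n_filters: int, n_blocks: int, c_out: int,
                 kernel: tuple[int, int] = (3, 3), symmetrize: bool = True,
                 seed: int = 0, dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        self.symmetrize = symmetrize
        self.c_in, self.c_out = c_in, c_out
        self.entry = Conv(c_in, n_filters, kernel, rng, dtype)
        self.blocks = [
            (Conv(n_filters, n_filters, kernel, rng, dtype),
             Conv(n_filters, n_filters, kernel, rng, dtype))
            for _ in range(n_blocks)
        ]
        self.final = Conv(n_filters, c_out, kernel, rng, dtype)
        self._cache: dict | None = None

    # -- introspection ------------------------------------------------------

    @property
    def conv_layers(self) -> list[Conv]:
        layers = [self.entry]
        for c1, c2 in self.blocks:
            layers.extend((c1, c2))
        layers.append(self.final)
        return layers

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_layers)

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_parameters for layer in self.conv_layers)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities, (c_out, H, W), softmax over channels."""
        if x.ndim != 3 or x.shape[0] != self.c_in:
            raise ValueError(
                f"input must be ({self.c_in}, H, W); got {x.shape}"
            )
        cache: dict = {"relu": [], "block_in": []}
        h = _relu(self.entry.forward(x, train))
        if train:
            cache["relu"].append(h > 0)
        for c1, c2 in self.blocks:
            if train:
                cache["block_in"].append(h)
            a = _relu(c1.forward(h, train))
            if train:
                cache["relu"].append(a > 0)
            f = c2.forward(a, train)
            h = _relu(f + h)
            if train:
                cache["relu"].append(h > 0)
        if self.symmetrize:
            h = _sym(h)
        logits = self.final.forward(h, train)
        if self.symmetrize:
            logits = _sym(logits)
        z = logits - logits.max(axis=0, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=0, keepdims=True)
        if train:
            cache["probs"] = probs
            self._cache = cache
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the (pre-softmax) logits."""
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        cache = self._cache
        relu_masks = cache["relu"]
        if self.symmetrize:
            dlogits = _sym(dlogits)
        dh = self.final.backward(dlogits)
        if self.symmetrize:
            dh = _sym(dh)
        for idx in range(len(self.blocks) - 1, -1, -1):
            c1, c2 = self.blocks[idx]
            dh = dh * relu_masks[1 + 2 * idx + 1]
            da = c2.backward(dh)
            da = da * relu_masks[1 + 2 * idx]
            dh = dh + c1.backward(da)
        dh = dh * relu_masks[0]
        self.entry.backward(dh)
        self._cache = None

    # -- loss and optimisation ---------------------------------------------

    def loss_and_grad(self, probs: np.ndarray, labels: np.ndarray,
                      class_weights: np.ndarray) -> tuple[float, np.ndarray]:
        """Weighted softmax cross-entropy; returns (loss, dlogits).

        ``labels`` holds class indices; positions whose class weight is zero
        (the ignore mask) contribute neither loss nor gradient.  The loss is
        normalised by the total weight.
        """
        w = class_weights[labels].astype(probs.dtype)
        total = float(w.sum())
        if total == 0.0:
            return 0.0, np.zeros_like(probs)
        eps = np.finfo(probs.dtype).tiny
        picked = np.take_along_axis(probs, labels[None], axis=0)[0]
        loss = float((w * -np.log(picked + eps)).sum() / total)
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, labels[None], 1.0, axis=0)
        dlogits = (probs - onehot) * (w / total)[None]
        return loss, dlogits

    def zero_grad(self) -> None:
        for layer in self.conv_layers:
            layer.zero_grad()

    def sgd_step(self, lr: float, momentum: float, weight_decay: float) -> None:
        for layer in self.conv_layers:
            layer.sgd_step(lr, momentum, weight_decay)

    # -- (de)serialisation ---------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers:
            out.extend((layer.W.copy(), layer.b.copy()))
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        layers = self.conv_layers
        if len(weights) != 2 * len(layers):
            raise ValueError("weight list does not match architecture")
        for layer, W, b in zip(layers, weights[0::2], weights[1::2]):
            if W.shape != layer.W.shape or b.shape != layer.b.shape:
                raise ValueError("weight shapes do not match architecture")
            layer.W = W.astype(layer.W.dtype).copy()
            layer.b = b.astype(layer.b.dtype).copy()
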