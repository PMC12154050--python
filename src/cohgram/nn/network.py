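"""Sequential container, softmax cross-entropy, Adam."""

from __future__ import annotations

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(probs + 1e-12)).sum() / n)
    return loss, (probs - onehot) / n


class Sequential:
    """Plain layer stack with shape audit and weight (de)serialisation."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    def output_shapes(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Per-layer output shapes (without the batch axis) for a given
        input batch — the architecture audit."""
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            shapes.append(tuple(x.shape[1:]))
        return shapes

    def n_parameters(self) -> int:
        return sum(int(p.size) for p, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            p[...] = w


class Adam:
    """Adam optimiser over a model's (value, gradient) parameter pairs."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = model.parameters()
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.model.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
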