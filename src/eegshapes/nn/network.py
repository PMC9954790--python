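"""Sequential network container, Adam optimiser, weight (de)serialisation."""

from __future__ import annotations

import numpy as np

from .layers import Dropout, Layer

__all__ = ["Network", "Adam", "softmax_cross_entropy"]


class Network:
    """A plain feed-forward stack of layers.

    ``input_extents`` records the per-item geometry the network was built
    for (excluding the batch axis) so callers can validate data layout
    before training or inference.
    """

    def __init__(self, layers: list[Layer], input_extents: tuple[int, ...]) -> None:
        self.layers = layers
        self.input_extents = tuple(int(e) for e in input_extents)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if tuple(x.shape[1:]) != self.input_extents:
            raise ValueError(
                f"input geometry {tuple(x.shape[1:])} does not match the "
                f"network's expected extents {self.input_extents}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference forward pass in chunks (dropout off, BN frozen)."""
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        """Copies of all trainable parameters and BN running statistics."""
        state = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            for buf in ("running_mean", "running_var"):
                if hasattr(layer, buf):
                    state.append(getattr(layer, buf).copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        i = len(params)
        for layer in self.layers:
            for buf in ("running_mean", "running_var"):
                if hasattr(layer, buf):
                    setattr(layer, buf, state[i].copy())
                    i += 1

    def seed_dropout(self, seed: int) -> None:
        """Give every dropout layer a fresh deterministic stream."""
        for k, layer in enumerate(self.layers):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(np.random.SeedSequence([seed, k]))

    # -- persistence --------------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez(path, **{f"w{i}": w for i, w in enumerate(self.get_weights())})

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            self.set_weights([z[f"w{i}"] for i in range(len(z.files))])


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(
        self,
        params: list[np.ndarray],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = float(learning_rate)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.epsilon = float(epsilon)
        self.m = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.epsilon)


def softmax_cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the probs.

    The returned gradient feeds the softmax layer's backward pass, which
    reduces it to the numerically exact ``(p - y) / n`` at the logits.
    """
    n = probs.shape[0]
    p = np.clip(probs, 1e-12, None)
    loss = float(-(onehot * np.log(p)).sum() / n)
    dprobs = -(onehot / p) / n
    return loss, dprobs.astype(probs.dtype)
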