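"""Network container: forward/backward, parameter counting, SGD-momentum."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param, iter_layers


class Network:
    """A trainable network built from a root :class:`Layer`.

    ``root`` must map (B, H, W, C) inputs to (B, n_classes) softmax
    probabilities. ``feature_layer`` marks where feature extraction reads
    activations (the global-average-pool output); ``last_conv`` marks the
    deepest convolutional layer used by Grad-CAM.
    """

    def __init__(self, root: Layer, *, name: str = "network",
                 feature_layer: Layer | None = None,
                 last_conv: Layer | None = None,
                 spec=None, seed: int | None = None):
        self.root = root
        self.name = name
        self.feature_layer = feature_layer
        self.last_conv = last_conv
        self.spec = spec
        self.seed = seed

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return self.root.forward(x, training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.root.backward(dout)

    # -- parameters --------------------------------------------------------

    def params(self) -> list[Param]:
        return list(self.root.params())

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def layers(self):
        return iter_layers(self.root)

    # -- serialization -----------------------------------------------------

    def save_weights(self, path) -> None:
        """Checkpoint parameters and batchnorm running statistics (.npz)."""
        from .layers import BatchNorm2D

        arrays = {f"param{i:04d}": p.value for i, p in enumerate(self.params())}
        bns = [l for l in iter_layers(self.root) if isinstance(l, BatchNorm2D)]
        for i, bn in enumerate(bns):
            arrays[f"bn{i:04d}.mean"] = bn.running_mean
            arrays[f"bn{i:04d}.var"] = bn.running_var
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        from .layers import BatchNorm2D

        data = np.load(path)
        for i, p in enumerate(self.params()):
            value = data[f"param{i:04d}"]
            if value.shape != p.value.shape:
                raise ValueError(f"checkpoint mismatch at parameter {i}")
            p.value = value.copy()
        bns = [l for l in iter_layers(self.root) if isinstance(l, BatchNorm2D)]
        for i, bn in enumerate(bns):
            bn.running_mean = data[f"bn{i:04d}.mean"].copy()
            bn.running_var = data[f"bn{i:04d}.var"].copy()

    # -- training loss -----------------------------------------------------

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch; leaves gradients accumulated.

        ``y`` holds integer class indices. The softmax output layer is part
        of the network, so the incoming gradient is d(loss)/d(probabilities).
        """
        probs = self.forward(x, training=True)
        n = probs.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + eps)))
        dprobs = np.zeros_like(probs)
        dprobs[np.arange(n), y] = -1.0 / (probs[np.arange(n), y] + eps) / n
        self.backward(dprobs)
        return loss


class SGDMomentum:
    """Classical momentum SGD: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, params: list[Param], lr: float, momentum: float):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
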