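"""First-order optimisers operating on the layer library's parameter dicts."""

from __future__ import annotations

import numpy as np

from .layers import Layer, collect_parameter_layers


class Adam:
    """Adam with bias correction (Kingma & Ba defaults except the learning rate)."""

    def __init__(self, layers, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers: list[Layer] = collect_parameter_layers(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, layers, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.layers: list[Layer] = collect_parameter_layers(layers)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self._vel):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay and k == "W":
                    g = g + self.weight_decay * p
                vel[k] = self.momentum * vel[k] - self.lr * g
                p += vel[k]
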