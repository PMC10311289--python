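"""Adam optimizer and gradient clipping for flat parameter collections."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


def iter_params(tree) -> list[Tensor]:
    """Flatten nested dicts/lists/dataclasses of Tensors into a stable order."""
    out: list[Tensor] = []
    if isinstance(tree, Tensor):
        out.append(tree)
    elif isinstance(tree, dict):
        for key in sorted(tree):
            out.extend(iter_params(tree[key]))
    elif isinstance(tree, (list, tuple)):
        for item in tree:
            out.extend(iter_params(item))
    elif hasattr(tree, "__dataclass_fields__"):
        for name in sorted(tree.__dataclass_fields__):
            out.extend(iter_params(getattr(tree, name)))
    return out


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad**2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = iter_params(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
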