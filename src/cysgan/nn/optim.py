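"""AdamW optimiser and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


def cosine_annealed_lr(base_lr: float, step: int, total_steps: int) -> float:
    """lr(t) = base * (1 + cos(pi * t / T)) / 2, annealed to 0 at t = T."""
    if total_steps <= 0:
        return base_lr
    t = min(max(step, 0), total_steps)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * t / total_steps))


class AdamW:
    """Decoupled weight decay Adam over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= lr * (update + self.weight_decay * p.data)

    def state_dict(self) -> dict:
        state = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m.{i}"] = m.copy()
            state[f"v.{i}"] = v.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i][...] = state[f"m.{i}"]
            self.v[i][...] = state[f"v.{i}"]
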