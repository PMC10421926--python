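"""Parameterized building blocks: linear maps, MLPs, and a GRU cell."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, add, getitem, matmul, mul, relu, sigmoid, tanh

_ACT = {"relu": relu, "tanh": tanh, "sigmoid": sigmoid, "linear": lambda x: x}


class Module:
    """Base class tracking parameters recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(a.tobytes())
        return h.hexdigest()[:16]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / max(n_in, 1))
        self.W = Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)


class MLP(Module):
    """Fully connected stack; hidden activation relu, output configurable."""

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        hidden_activation: str = "relu",
        output_activation: str = "linear",
    ):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self._hidden = _ACT[hidden_activation]
        self._output = _ACT[output_activation]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self._hidden(layer(x))
        return self._output(self.layers[-1](x))


class GRUCell(Module):
    """Gated recurrent unit; one step per call, weights shared across steps."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.x2h = Linear(n_in, 3 * n_hidden, rng)
        self.h2h = Linear(n_hidden, 3 * n_hidden, rng)

    def step(self, x: Tensor | None, h: Tensor, gx: Tensor | None = None) -> Tensor:
        """One GRU step.  ``gx`` may carry a precomputed input transform
        (x2h(x)), letting callers batch that matmul across steps."""
        H = self.n_hidden
        if gx is None:
            gx = self.x2h(x)
        gh = self.h2h(h)
        xz = getitem(gx, (slice(None), slice(0, H)))
        xr = getitem(gx, (slice(None), slice(H, 2 * H)))
        xn = getitem(gx, (slice(None), slice(2 * H, 3 * H)))
        hz = getitem(gh, (slice(None), slice(0, H)))
        hr = getitem(gh, (slice(None), slice(H, 2 * H)))
        hn = getitem(gh, (slice(None), slice(2 * H, 3 * H)))
        z = sigmoid(add(xz, hz))
        r = sigmoid(add(xr, hr))
        n = tanh(add(xn, mul(r, hn)))
        one = Tensor(1.0)
        return add(mul(add(one, -z), n), mul(z, h))

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden)))
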